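"""Synthetic 1D NMR data: spectra sets, FIDs and on-disk vendor fixtures.

The generator emulates the artifacts the processing pipeline exists to fix:
per-sample chemical-shift jitter (pH/ionic-strength peak wander), slowly
varying polynomial baselines, additive white noise, and factor-dependent
peak intensities.  Lineshapes are Lorentzian only, the natural liquid-state
1D model, which keeps half-height checks analytic.  Multiplet intensity
ratios are first-order binomial: singlet 1, doublet 1:1, triplet 1:2:1.

Randomness is one stream per plan, consumed in a documented order —
jitter first (sample-major), then noise (sample-major) — so identical
plans are bit-identical and partial re-simulation is reproducible.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree as ET

import numpy as np

from .types import AxisSpec, FidRecord, SampleTable, SpectrumSet

__all__ = [
    "PeakSpec",
    "SimulationPlan",
    "simulate_spectrum_set",
    "simulate_fid",
    "write_bruker_fixture",
    "write_bruker_1r_fixture",
    "write_varian_fixture",
    "write_nmrml_fixture",
    "write_sample_table",
    "write_raw_batch",
]

_MULTIPLET_WEIGHTS = {1: [1.0], 2: [0.5, 0.5], 3: [0.25, 0.5, 0.25]}


@dataclass(frozen=True)
class PeakSpec:
    """One resonance pattern: a singlet, doublet or triplet of Lorentzians."""

    center_ppm: float
    height: float
    width_hz: float
    multiplicity: int = 1
    j_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if self.width_hz <= 0:
            raise ValueError("width_hz must be > 0")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.multiplicity > 3:
            raise ValueError("multiplicity > 3 not supported (binomial ratios fixed)")

    def components(self, sfo_mhz: float) -> list[tuple[float, float]]:
        """Sub-peaks as (center_ppm, height) with binomial weights.

        The multiplet splitting ``j_hz`` is converted to ppm at the given
        spectrometer frequency; total pattern height budget is ``height``.
        """
        m = self.multiplicity
        weights = _MULTIPLET_WEIGHTS[m]
        j_ppm = self.j_hz / sfo_mhz
        offsets = [(k - (m - 1) / 2.0) * j_ppm for k in range(m)]
        return [(self.center_ppm + off, self.height * w) for off, w in zip(offsets, weights)]


@dataclass(frozen=True)
class SimulationPlan:
    """Everything needed to draw one reproducible synthetic spectra set."""

    n_samples: int
    peaks: tuple[PeakSpec, ...]
    ppm_jitter_sd: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    noise_sd: float = 0.0
    factor_assignment: Optional[dict[str, str]] = None
    group_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd < 0 or self.ppm_jitter_sd < 0:
            raise ValueError("noise_sd and ppm_jitter_sd must be >= 0")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        if self.factor_assignment is not None and len(self.factor_assignment) != self.n_samples:
            raise ValueError("factor_assignment must name every sample")

    def sample_ids(self) -> list[str]:
        if self.factor_assignment is not None:
            return list(self.factor_assignment)
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def levels(self) -> list[str]:
        if self.factor_assignment is None:
            return ["all"] * self.n_samples
        return [self.factor_assignment[s] for s in self.sample_ids()]

    def height_matrix(self) -> np.ndarray:
        """Per-sample, per-peak heights after group effects (n_samples x n_peaks)."""
        levels = self.levels()
        h = np.empty((self.n_samples, len(self.peaks)))
        for i, lev in enumerate(levels):
            for j, pk in enumerate(self.peaks):
                h[i, j] = pk.height * self.group_effects.get((lev, j), 1.0)
        return h


def _validate_peaks(plan: SimulationPlan, axis: AxisSpec) -> None:
    for pk in plan.peaks:
        for c, _ in pk.components(axis.sfo_mhz):
            if not (axis.ppm_min <= c <= axis.ppm_max):
                raise ValueError(
                    f"peak component at {c:.4f} ppm falls outside axis "
                    f"[{axis.ppm_min:.4f}, {axis.ppm_max:.4f}]"
                )


def _draw_jitter_and_noise(plan: SimulationPlan, n_points: int):
    """Single RNG stream: jitter first, then noise, both sample-major."""
    rng = np.random.default_rng(plan.seed)
    jitter = rng.normal(0.0, plan.ppm_jitter_sd, size=(plan.n_samples, len(plan.peaks))) \
        if plan.ppm_jitter_sd > 0 else np.zeros((plan.n_samples, len(plan.peaks)))
    noise = rng.normal(0.0, plan.noise_sd, size=(plan.n_samples, n_points)) \
        if plan.noise_sd > 0 else np.zeros((plan.n_samples, n_points))
    return jitter, noise


def lorentzian(ppm: np.ndarray, center: float, height: float, hwhm_ppm: float) -> np.ndarray:
    """Absorptive Lorentzian: height at center, height/2 at center +- hwhm."""
    u = (ppm - center) / hwhm_ppm
    return height / (1.0 + u * u)


def simulate_spectrum_set(plan: SimulationPlan, axis: AxisSpec) -> SpectrumSet:
    """Draw an N x P spectra set from a plan on the given axis.

    Each spectrum is the sum of Lorentzian sub-peaks (binomial multiplet
    weights), plus the polynomial baseline evaluated on a [-1, 1]-scaled
    ppm coordinate, plus white Gaussian noise.  Peak centers are
    ``center_ppm + jitter`` drawn once per (sample, peak).
    """
    _validate_peaks(plan, axis)
    ppm = axis.ppm_axis()
    jitter, noise = _draw_jitter_and_noise(plan, axis.n_points)
    heights = plan.height_matrix()

    # baseline on a scale-free coordinate so coefficients mean the same
    # thing for any axis window
    x = (ppm - axis.carrier_ppm) / (axis.sw_ppm / 2.0)
    baseline = np.polynomial.polynomial.polyval(x, plan.baseline_coeffs) \
        if plan.baseline_coeffs else 0.0

    mat = np.zeros((plan.n_samples, axis.n_points))
    for i in range(plan.n_samples):
        row = np.zeros(axis.n_points)
        for j, pk in enumerate(plan.peaks):
            hwhm_ppm = (pk.width_hz / 2.0) / axis.sfo_mhz
            scaled = PeakSpec(pk.center_ppm, 1.0, pk.width_hz, pk.multiplicity, pk.j_hz)
            for c, w in scaled.components(axis.sfo_mhz):
                row += lorentzian(ppm, c + jitter[i, j], heights[i, j] * w, hwhm_ppm)
        mat[i] = row + baseline + noise[i]

    import pandas as pd
    table = SampleTable(pd.DataFrame({"sample_id": plan.sample_ids(), "group": plan.levels()}))
    return SpectrumSet(intensities=mat, ppm_axis=ppm, sample_table=table)


def simulate_fid(plan: SimulationPlan, axis: AxisSpec, sample_index: int = 0) -> FidRecord:
    """Time-domain counterpart of one sample of :func:`simulate_spectrum_set`.

    The FID is ``sum_k a_k * exp(i*2*pi*nu_k*t - pi*w_k*t)`` sampled at the
    dwell time implied by the spectral width, with ``nu_k`` the sub-peak
    offset from the carrier (Hz) and ``w_k`` its FWHM (Hz).  Amplitudes are
    scaled by ``pi*w_k*dwell`` so the transformed apex recovers the plan
    height.  Polynomial baselines have no time-domain counterpart and are
    ignored here; noise (if any) is added as complex white noise of the
    plan's ``noise_sd``.
    """
    _validate_peaks(plan, axis)
    if not 0 <= sample_index < plan.n_samples:
        raise IndexError("sample_index out of range")
    jitter, _ = _draw_jitter_and_noise(plan, axis.n_points)
    heights = plan.height_matrix()

    n = axis.n_points
    dt = axis.dwell_s
    t = np.arange(n) * dt
    sig = np.zeros(n, dtype=np.complex128)
    for j, pk in enumerate(plan.peaks):
        scaled = PeakSpec(pk.center_ppm, 1.0, pk.width_hz, pk.multiplicity, pk.j_hz)
        for c, w in scaled.components(axis.sfo_mhz):
            nu = (c + jitter[sample_index, j] - axis.carrier_ppm) * axis.sfo_mhz
            amp = heights[sample_index, j] * w * (np.pi * pk.width_hz * dt)
            sig += amp * np.exp((2j * np.pi * nu - np.pi * pk.width_hz) * t)
    if plan.noise_sd > 0:
        rng = np.random.default_rng((plan.seed, 1, sample_index))
        sig += rng.normal(0, plan.noise_sd, n) + 1j * rng.normal(0, plan.noise_sd, n)

    return FidRecord(
        signal=sig,
        dwell_us=dt * 1e6,
        sfo_mhz=axis.sfo_mhz,
        sw_ppm=axis.sw_ppm,
        o1_hz=axis.carrier_ppm * axis.sfo_mhz,
        group_delay=0.0,
        vendor="synthetic",
        sample_id=plan.sample_ids()[sample_index],
    )


# ---------------------------------------------------------------------------
# On-disk vendor fixtures.  These writers produce the minimal files the
# corresponding readers in :mod:`spinproc.vendor_io` require; they are
# synthetic stand-ins for real acquisition directories.
# ---------------------------------------------------------------------------

def _jcamp_lines(params: dict) -> str:
    lines = ["##TITLE= synthetic fixture", "##JCAMPDX= 5.0"]
    for k, v in params.items():
        lines.append(f"##${k}= {v}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"


def write_bruker_fixture(fid: FidRecord, directory, byteorda: int = 0,
                         dtypa: int = 0) -> Path:
    """Write a minimal Bruker experiment directory (``acqus`` + ``fid``).

    ``dtypa`` 0 stores int32 words (values rounded; callers wanting exact
    round trips should scale heights so quantization is negligible),
    ``dtypa`` 2 stores float64.  ``byteorda`` 0 = little endian, 1 = big.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    td = 2 * fid.signal.size
    sw_hz = fid.sw_ppm * fid.sfo_mhz
    params = {
        "TD": td,
        "SW": f"{fid.sw_ppm:.6f}",
        "SW_h": f"{sw_hz:.6f}",
        "SFO1": f"{fid.sfo_mhz:.8f}",
        "O1": f"{fid.o1_hz:.4f}",
        "BYTORDA": byteorda,
        "DTYPA": dtypa,
        "GRPDLY": f"{fid.group_delay:.6f}",
    }
    (directory / "acqus").write_text(_jcamp_lines(params), encoding="utf-8")

    inter = np.empty(td, dtype=np.float64)
    inter[0::2] = fid.signal.real
    inter[1::2] = fid.signal.imag
    if dtypa == 0:
        word = np.round(inter).astype("<i4" if byteorda == 0 else ">i4")
    elif dtypa == 2:
        word = inter.astype("<f8" if byteorda == 0 else ">f8")
    else:
        raise ValueError(f"unsupported DTYPA {dtypa}")
    (directory / "fid").write_bytes(word.tobytes())
    return directory


def write_bruker_1r_fixture(spectrum: np.ndarray, ppm_axis: np.ndarray, directory,
                            sf_mhz: float = 500.0, nc_proc: int = 0,
                            byteordp: int = 0) -> Path:
    """Write a minimal Bruker processed directory (``procs`` + ``1r``).

    Stored integers are the spectrum divided by ``2**nc_proc`` (the reader
    rescales); the axis is encoded via OFFSET (ppm of the first point),
    SW_p (width in Hz) and SF (MHz).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    si = spectrum.size
    sw_ppm = float(ppm_axis[0] - ppm_axis[-1])
    params = {
        "SI": si,
        "OFFSET": f"{ppm_axis[0]:.6f}",
        "SW_p": f"{sw_ppm * sf_mhz:.6f}",
        "SF": f"{sf_mhz:.8f}",
        "NC_proc": nc_proc,
        "BYTORDP": byteordp,
        "DTYPP": 0,
    }
    (directory / "procs").write_text(_jcamp_lines(params), encoding="utf-8")
    stored = np.round(np.asarray(spectrum) / (2.0 ** nc_proc))
    word = stored.astype("<i4" if byteordp == 0 else ">i4")
    (directory / "1r").write_bytes(word.tobytes())
    return directory


_VARIAN_FILEHEADER = struct.Struct(">6l2hl")   # nblocks ntraces np ebytes tbytes bbytes vers_id status nbheaders
_VARIAN_BLOCKHEADER = struct.Struct(">4hl4f")  # scale status index mode ctcount lpval rpval lvl tlt
_S_DATA, _S_FLOAT, _S_32 = 0x1, 0x8, 0x4


def write_varian_fixture(fid: FidRecord, directory) -> Path:
    """Write a minimal Varian/Agilent directory (``procpar`` + ``fid``).

    Data are one big-endian float32 block of interleaved real/imaginary
    points; ``procpar`` carries np, sw, sfrq and tof in the vendor's
    name-line / value-line layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    npts = 2 * fid.signal.size
    sw_hz = fid.sw_ppm * fid.sfo_mhz
    # tof is the carrier offset from sfrq; the reader reconstructs o1 = tof
    lines = []
    for name, value in [("np", npts), ("sw", f"{sw_hz:.6f}"),
                        ("sfrq", f"{fid.sfo_mhz:.8f}"), ("tof", f"{fid.o1_hz:.4f}")]:
        lines.append(f"{name} 1 1 2 0 0 2 1 0 0 64")
        lines.append(f"1 {value}")
        lines.append("0")
    (directory / "procpar").write_text("\n".join(lines) + "\n", encoding="utf-8")

    inter = np.empty(npts, dtype=">f4")
    inter[0::2] = fid.signal.real
    inter[1::2] = fid.signal.imag
    data = inter.tobytes()
    ebytes, tbytes = 4, npts * 4
    fh = _VARIAN_FILEHEADER.pack(1, 1, npts, ebytes, tbytes,
                                 tbytes + _VARIAN_BLOCKHEADER.size,
                                 0, _S_DATA | _S_FLOAT | _S_32, 1)
    bh = _VARIAN_BLOCKHEADER.pack(0, _S_DATA | _S_FLOAT | _S_32, 1, 0, 1, 0.0, 0.0, 0.0, 0.0)
    (directory / "fid").write_bytes(fh + bh + data)
    return directory


def write_nmrml_fixture(fid: FidRecord, path, compressed: bool = False) -> Path:
    """Write a minimal nmrML XML file holding one 1D acquisition.

    The complex signal is stored little-endian complex128, base64-encoded,
    optionally zlib-compressed; acquisition parameters are carried as
    attributes the reader understands.
    """
    path = Path(path)
    raw = fid.signal.astype("<c16").tobytes()
    if compressed:
        raw = zlib.compress(raw)
    payload = base64.b64encode(raw).decode("ascii")

    root = ET.Element("nmrML")
    acq = ET.SubElement(root, "acquisition")
    a1 = ET.SubElement(acq, "acquisition1D")
    prm = ET.SubElement(a1, "acquisitionParameterSet", {
        "numberOfDataPoints": str(fid.signal.size),
        "sweepWidthPpm": f"{fid.sw_ppm:.8f}",
        "irradiationFrequencyMhz": f"{fid.sfo_mhz:.8f}",
        "carrierOffsetHz": f"{fid.o1_hz:.6f}",
        "groupDelay": f"{fid.group_delay:.6f}",
    })
    prm.set("sampleId", fid.sample_id or "sample")
    data = ET.SubElement(a1, "fidData", {
        "byteFormat": "complex128",
        "compressed": "true" if compressed else "false",
        "encodedLength": str(len(payload)),
    })
    data.text = payload
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)
    return path


def write_sample_table(table: SampleTable, path) -> Path:
    """Write the TSV metadata fixture: sample_id first, factors after."""
    path = Path(path)
    cols = ["sample_id"] + table.factor_names
    table.frame[cols].to_csv(path, sep="\t", index=False)
    return path


def write_raw_batch(plan: SimulationPlan, axis: AxisSpec, directory,
                    vendor: str = "bruker") -> Path:
    """Write a whole batch: one vendor FID directory per sample + samples.tsv.

    This is the raw-input layout the batch replay mode consumes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    rows = []
    for i, sid in enumerate(plan.sample_ids()):
        fid = simulate_fid(plan, axis, sample_index=i)
        sub = directory / sid
        if vendor == "bruker":
            write_bruker_fixture(fid, sub, dtypa=2)
        elif vendor == "varian":
            write_varian_fixture(fid, sub)
        else:
            raise ValueError(f"unknown vendor {vendor!r}")
        rows.append({"sample_id": sid, "group": plan.levels()[i]})
    pd.DataFrame(rows).to_csv(directory / "samples.tsv", sep="\t", index=False)
    return directory
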