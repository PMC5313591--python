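"""Readers for Bruker, Varian/Agilent and nmrML data, plus set assembly.

Every reader returns the common in-memory types from :mod:`spinproc.types`;
format errors raise :class:`FormatError` naming the offending file or key.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .types import FidRecord, SampleTable, SpectrumSet

__all__ = [
    "FormatError",
    "read_bruker_fid",
    "read_bruker_1r",
    "read_varian_fid",
    "read_nmrml",
    "read_sample_table",
    "assemble_spectrum_set",
    "subset_by_factor",
]


class FormatError(ValueError):
    """A vendor file is missing, truncated or internally inconsistent."""


# --- JCAMP-DX parameter files (acqus / procs) ------------------------------

def _read_jcamp(path: Path) -> dict[str, str]:
    if not path.is_file():
        raise FormatError(f"missing parameter file: {path}")
    params: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        if line.startswith("##$") and "=" in line:
            key, _, value = line[3:].partition("=")
            params[key.strip()] = value.strip()
    return params


def _jcamp_float(params: dict, key: str, path: Path) -> float:
    if key not in params:
        raise FormatError(f"missing key {key} in {path}")
    return float(params[key])


# DECIM/DSPFVS lookup for older Bruker consoles that predate the GRPDLY
# parameter (standard published table, firmware versions 10-12).
_DSP_TABLE = {
    (10, 2): 44.75, (10, 3): 33.5, (10, 4): 66.625, (10, 6): 59.083,
    (10, 8): 68.563, (10, 12): 60.375, (10, 16): 69.531, (10, 24): 61.021,
    (10, 32): 70.016, (10, 48): 61.344, (10, 64): 70.258, (10, 96): 61.505,
    (10, 128): 70.379, (10, 192): 61.586, (10, 256): 70.439, (10, 384): 61.626,
    (10, 512): 70.470, (10, 768): 61.647, (10, 1024): 70.485, (10, 1536): 61.657,
    (10, 2048): 70.492,
    (11, 2): 46.0, (11, 3): 36.5, (11, 4): 48.0, (11, 6): 50.167,
    (11, 8): 53.25, (11, 12): 69.5, (11, 16): 72.25, (11, 24): 70.167,
    (11, 32): 72.75, (11, 48): 70.5, (11, 64): 73.0, (11, 96): 70.667,
    (11, 128): 72.5, (11, 192): 71.333, (11, 256): 72.25, (11, 384): 71.667,
    (11, 512): 72.125, (11, 768): 71.833, (11, 1024): 72.063, (11, 1536): 71.917,
    (11, 2048): 72.031,
    (12, 2): 46.311, (12, 3): 36.53, (12, 4): 47.87, (12, 6): 50.229,
    (12, 8): 53.289, (12, 12): 69.551, (12, 16): 71.6, (12, 24): 70.184,
    (12, 32): 72.138, (12, 48): 70.528, (12, 64): 72.348, (12, 96): 70.7,
    (12, 128): 72.524,
}


def read_bruker_fid(directory) -> FidRecord:
    """Read a Bruker experiment directory (``fid`` + ``acqus``) into a FidRecord.

    Group delay comes from GRPDLY when present (and >= 0), else the
    DECIM/DSPFVS lookup table, else 0.
    """
    directory = Path(directory)
    acqus = directory / "acqus"
    fid_path = directory / "fid"
    params = _read_jcamp(acqus)
    if not fid_path.is_file():
        raise FormatError(f"missing fid file: {fid_path}")

    td = int(_jcamp_float(params, "TD", acqus))
    sw_ppm = _jcamp_float(params, "SW", acqus)
    sfo = _jcamp_float(params, "SFO1", acqus)
    o1 = float(params.get("O1", "0"))
    byteorda = int(float(params.get("BYTORDA", "0")))
    dtypa = int(float(params.get("DTYPA", "0")))

    endian = "<" if byteorda == 0 else ">"
    if dtypa == 0:
        dtype, wordsize = np.dtype(endian + "i4"), 4
    elif dtypa == 2:
        dtype, wordsize = np.dtype(endian + "f8"), 8
    else:
        raise FormatError(f"unknown DTYPA {dtypa} in {acqus}")

    raw = fid_path.read_bytes()
    if len(raw) < td * wordsize:
        raise FormatError(
            f"fid file {fid_path} holds {len(raw)} bytes, "
            f"TD={td} requires {td * wordsize}"
        )
    words = np.frombuffer(raw[: td * wordsize], dtype=dtype).astype(np.float64)
    signal = words[0::2] + 1j * words[1::2]

    if "GRPDLY" in params and float(params["GRPDLY"]) >= 0:
        group_delay = float(params["GRPDLY"])
    elif "DECIM" in params and "DSPFVS" in params:
        key = (int(float(params["DSPFVS"])), int(float(params["DECIM"])))
        group_delay = _DSP_TABLE.get(key, 0.0)
    else:
        group_delay = 0.0

    sw_hz = sw_ppm * sfo
    return FidRecord(
        signal=signal,
        dwell_us=1e6 / sw_hz,
        sfo_mhz=sfo,
        sw_ppm=sw_ppm,
        o1_hz=o1,
        group_delay=group_delay,
        vendor="bruker",
        sample_id=directory.name,
    )


def read_bruker_1r(directory) -> tuple[np.ndarray, np.ndarray]:
    """Read a Bruker processed spectrum (``1r`` + ``procs``).

    Returns ``(spectrum, ppm_axis)``.  Stored integers are scaled by
    ``2**NC_proc``; the axis is a uniform descending grid with the first
    point at OFFSET and spacing ``(SW_p/SF) / (SI - 1)``.
    """
    directory = Path(directory)
    procs = directory / "procs"
    r1 = directory / "1r"
    params = _read_jcamp(procs)
    if not r1.is_file():
        raise FormatError(f"missing 1r file: {r1}")

    si = int(_jcamp_float(params, "SI", procs))
    offset = _jcamp_float(params, "OFFSET", procs)
    sw_p_hz = _jcamp_float(params, "SW_p", procs)
    sf = _jcamp_float(params, "SF", procs)
    nc_proc = int(float(params.get("NC_proc", "0")))
    byteordp = int(float(params.get("BYTORDP", "0")))

    endian = "<" if byteordp == 0 else ">"
    raw = r1.read_bytes()
    if len(raw) < si * 4:
        raise FormatError(f"1r file {r1} holds {len(raw)} bytes, SI={si} requires {si * 4}")
    stored = np.frombuffer(raw[: si * 4], dtype=endian + "i4").astype(np.float64)
    spectrum = stored * (2.0 ** nc_proc)

    sw_ppm = sw_p_hz / sf
    ppm_axis = offset - np.arange(si) * (sw_ppm / (si - 1))
    return spectrum, ppm_axis


# --- Varian/Agilent --------------------------------------------------------

_V_FILEHEADER = struct.Struct(">6l2hl")
_V_BLOCKHEADER = struct.Struct(">4hl4f")
_S_FLOAT, _S_32 = 0x8, 0x4


def _read_procpar(path: Path) -> dict[str, str]:
    if not path.is_file():
        raise FormatError(f"missing procpar file: {path}")
    values: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8", errors="replace").splitlines()
    i = 0
    while i < len(lines) - 1:
        head = lines[i].split()
        if head and head[0].isidentifier():
            body = lines[i + 1].split()
            if len(body) >= 2 and body[0].isdigit():
                values[head[0]] = body[1].strip('"')
                i += 2
                continue
        i += 1
    return values


def read_varian_fid(directory) -> FidRecord:
    """Read a Varian/Agilent directory (big-endian block-format ``fid`` + ``procpar``)."""
    directory = Path(directory)
    procpar = _read_procpar(directory / "procpar")
    fid_path = directory / "fid"
    if not fid_path.is_file():
        raise FormatError(f"missing fid file: {fid_path}")
    for key in ("np", "sw", "sfrq"):
        if key not in procpar:
            raise FormatError(f"missing procpar key {key!r} in {directory / 'procpar'}")
    npts = int(float(procpar["np"]))
    sw_hz = float(procpar["sw"])
    sfrq = float(procpar["sfrq"])
    tof = float(procpar.get("tof", "0"))

    raw = fid_path.read_bytes()
    if len(raw) < _V_FILEHEADER.size:
        raise FormatError(f"fid file {fid_path} too short for a file header")
    nblocks, ntraces, np_hdr, ebytes, tbytes, bbytes, _, status, nbheaders = \
        _V_FILEHEADER.unpack_from(raw, 0)
    if np_hdr != npts:
        raise FormatError(
            f"np mismatch: procpar says {npts}, file header says {np_hdr}"
        )
    if status & _S_FLOAT:
        dtype = np.dtype(">f4")
    elif status & _S_32:
        dtype = np.dtype(">i4")
    else:
        dtype = np.dtype(">i2")
    expected = _V_FILEHEADER.size + nblocks * (nbheaders * _V_BLOCKHEADER.size + tbytes * ntraces)
    if len(raw) < expected:
        raise FormatError(f"fid file {fid_path} truncated: {len(raw)} < {expected} bytes")

    chunks = []
    off = _V_FILEHEADER.size
    for _ in range(nblocks):
        off += nbheaders * _V_BLOCKHEADER.size
        block = np.frombuffer(raw, dtype=dtype, count=npts * ntraces, offset=off)
        chunks.append(block.astype(np.float64))
        off += tbytes * ntraces
    words = np.concatenate(chunks)
    signal = words[0::2] + 1j * words[1::2]

    return FidRecord(
        signal=signal,
        dwell_us=1e6 / sw_hz,
        sfo_mhz=sfrq,
        sw_ppm=sw_hz / sfrq,
        o1_hz=tof,
        group_delay=0.0,
        vendor="varian",
        sample_id=directory.name,
    )


# --- nmrML -----------------------------------------------------------------

def _strip_ns(tag: str) -> str:
    return tag.rpartition("}")[2]


def read_nmrml(path) -> FidRecord:
    """Read the first 1D acquisition from an nmrML XML file."""
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"missing nmrML file: {path}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()

    if any(_strip_ns(el.tag) == "acquisition2D" for el in root.iter()):
        raise FormatError("unsupported dimensionality: 2D acquisitions are not handled")

    acq = next((el for el in root.iter() if _strip_ns(el.tag) == "acquisition1D"), None)
    if acq is None:
        raise FormatError(f"no acquisition1D element in {path}")
    prm = next((el for el in acq.iter() if _strip_ns(el.tag) == "acquisitionParameterSet"), None)
    data = next((el for el in acq.iter() if _strip_ns(el.tag) == "fidData"), None)
    if prm is None or data is None:
        raise FormatError(f"acquisitionParameterSet/fidData missing in {path}")

    try:
        n = int(prm.get("numberOfDataPoints"))
        sw_ppm = float(prm.get("sweepWidthPpm"))
        sfo = float(prm.get("irradiationFrequencyMhz"))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"acquisition parameters missing/invalid in {path}") from exc
    o1 = float(prm.get("carrierOffsetHz", "0"))
    gd = float(prm.get("groupDelay", "0"))

    byte_format = data.get("byteFormat", "complex128")
    if byte_format != "complex128":
        raise FormatError(f"unsupported byteFormat {byte_format!r}")
    raw = base64.b64decode(data.text or "")
    if data.get("compressed", "false") == "true":
        raw = zlib.decompress(raw)
    signal = np.frombuffer(raw, dtype="<c16")
    if signal.size != n:
        raise FormatError(
            f"payload holds {signal.size} points, numberOfDataPoints says {n}"
        )

    sw_hz = sw_ppm * sfo
    return FidRecord(
        signal=signal.astype(np.complex128),
        dwell_us=1e6 / sw_hz,
        sfo_mhz=sfo,
        sw_ppm=sw_ppm,
        o1_hz=o1,
        group_delay=gd,
        vendor="nmrml",
        sample_id=prm.get("sampleId", path.stem),
    )


# --- metadata + assembly ---------------------------------------------------

def read_sample_table(path) -> SampleTable:
    """Read the UTF-8 TSV metadata table: header row, sample_id first column."""
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"missing sample table: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"sample table {path} needs sample_id + >=1 factor column")
    frame = frame.rename(columns={frame.columns[0]: "sample_id"})
    return SampleTable(frame)


def assemble_spectrum_set(spectra: list[tuple[str, np.ndarray, np.ndarray]],
                          sample_table: SampleTable) -> SpectrumSet:
    """Stack per-sample spectra into one SpectrumSet ordered as the table.

    ``spectra`` is a list of ``(sample_id, intensities, ppm_axis)``.  All
    spectra must share one axis; rows follow sample-table order regardless
    of load order.
    """
    by_id = {}
    for sid, y, ax in spectra:
        if sid in by_id:
            raise ValueError(f"duplicate spectrum for sample_id {sid!r}")
        by_id[sid] = (np.asarray(y, dtype=np.float64), np.asarray(ax, dtype=np.float64))

    missing = [sid for sid in by_id if sid not in set(sample_table.sample_ids)]
    if missing:
        raise ValueError(f"spectra lack metadata rows: {sorted(missing)}")
    absent = [sid for sid in sample_table.sample_ids if sid not in by_id]
    if absent:
        raise ValueError(f"metadata rows lack spectra: {absent}")

    ref_id = sample_table.sample_ids[0]
    ref_axis = by_id[ref_id][1]
    p = ref_axis.size
    bad = [sid for sid, (y, ax) in by_id.items()
           if y.size != p or ax.size != p]
    if bad:
        raise ValueError(
            f"point-count mismatch (expected {p} points): {sorted(bad)}"
        )
    off_axis = [sid for sid, (_, ax) in by_id.items()
                if not np.allclose(ax, ref_axis, rtol=0, atol=1e-9 * abs(ref_axis[0] - ref_axis[-1]))]
    if off_axis:
        raise ValueError(f"ppm-axis mismatch: {sorted(off_axis)}")

    mat = np.vstack([by_id[sid][0] for sid in sample_table.sample_ids])
    return SpectrumSet(intensities=mat, ppm_axis=ref_axis.copy(), sample_table=sample_table)


def subset_by_factor(spectrum_set: SpectrumSet, factor: str, level: str) -> np.ndarray:
    """Order-preserving row indices of the samples at one factor level."""
    table = spectrum_set.sample_table
    if factor not in table.factor_names:
        raise KeyError(f"unknown factor {factor!r}; have {table.factor_names}")
    col = table.frame[factor].astype(str)
    if level not in set(col):
        raise KeyError(f"level {level!r} absent from factor {factor!r}")
    return np.nonzero((col == level).to_numpy())[0]
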