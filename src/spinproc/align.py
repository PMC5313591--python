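"""Chemical-shift calibration and zone-wise resonance alignment.

Peak positions wander between samples (pH, ionic strength, temperature),
so spectra are re-aligned zone by zone: an integer-shift least-squares
aligner for general regions, and a parametric time warping (PTW) aligner —
a low-order polynomial axis warp — for regions where every spectrum shows
the same peak pattern.  Both can act on the full set or on the subset of
samples sharing one experimental-factor level, each subset against its own
mean reference.

An accepted alignment never increases the dispersion statistic (mean
across-spectra standard deviation inside the zone); when it would, the data
are returned unchanged with a warning in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .types import MacroCommand, PpmZone, SpectrumSet, resolve_selection

__all__ = ["AlignmentReport", "calibrate", "align_zone_ls", "align_zone_ptw", "dispersion"]


@dataclass
class AlignmentReport:
    """QC record of one alignment pass."""

    zone: PpmZone
    method: str
    per_spectrum_shift: dict       # row index -> integer shift or warp coefficients
    dispersion_before: float
    dispersion_after: float
    warnings: list = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return self.dispersion_after <= self.dispersion_before


def dispersion(spectrum_set: SpectrumSet, zone: PpmZone,
               rows: Optional[np.ndarray] = None) -> float:
    """Mean over in-zone axis points of the across-spectra standard deviation."""
    idx = spectrum_set.zone_indices(zone)
    sub = spectrum_set.intensities[np.ix_(
        rows if rows is not None else np.arange(spectrum_set.n_spectra), idx)]
    return float(np.mean(np.std(sub, axis=0)))


def _check_not_excluded(spectrum_set: SpectrumSet, zone: PpmZone) -> None:
    for ex in spectrum_set.excluded_zones:
        if zone.overlaps(ex):
            raise ValueError(
                f"zone [{zone.ppm_min}, {zone.ppm_max}] overlaps excluded zone "
                f"[{ex.ppm_min}, {ex.ppm_max}]")


def calibrate(spectrum_set: SpectrumSet, zone: PpmZone, ref_ppm: float) -> SpectrumSet:
    """Shift each spectrum so the apex inside ``zone`` lands on ``ref_ppm``.

    The shift is a whole-spectrum integer-point translation; vacated edge
    points are zero-filled.  An apex sitting exactly on the zone edge is
    ambiguous (the true maximum may lie outside) and raises, naming the
    spectrum.
    """
    out = spectrum_set.copy()
    idx = out.zone_indices(zone)
    target = out.index_of(ref_ppm)
    for i in range(out.n_spectra):
        seg = out.intensities[i, idx]
        apex_local = int(np.argmax(seg))
        if apex_local in (0, seg.size - 1):
            sid = out.sample_table.sample_ids[i]
            raise ValueError(
                f"calibration apex at zone edge for sample {sid!r}; widen the zone")
        shift = target - int(idx[apex_local])
        if shift:
            row = np.roll(out.intensities[i], shift)
            if shift > 0:
                row[:shift] = 0.0
            else:
                row[shift:] = 0.0
            out.intensities[i] = row
    out.provenance.append(MacroCommand(
        "calibrate", {"ppm_min": zone.ppm_min, "ppm_max": zone.ppm_max,
                      "ref_ppm": ref_ppm}))
    return out


def _shifted_segment(seg: np.ndarray, s: int) -> np.ndarray:
    """Segment translated by s points; vacated points take the nearest edge value."""
    out = np.empty_like(seg)
    if s == 0:
        out[:] = seg
    elif s > 0:
        out[s:] = seg[:-s]
        out[:s] = seg[0]
    else:
        out[:s] = seg[-s:]
        out[s:] = seg[-1]
    return out


def align_zone_ls(spectrum_set: SpectrumSet, zone: PpmZone,
                  selection=None, max_shift: int = 20
                  ) -> tuple[SpectrumSet, AlignmentReport]:
    """Integer-shift least-squares alignment of one zone against the mean.

    Per spectrum, the shift in ``[-max_shift, max_shift]`` minimizing the
    squared difference to the selection's mean segment is applied within
    the zone (vacated points take the zone-edge value; ties break toward the
    smaller magnitude).  A best shift saturating at ``+-max_shift`` is
    treated as out of range: that spectrum is left unchanged with a warning.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    _check_not_excluded(spectrum_set, zone)
    out = spectrum_set.copy()
    idx = out.zone_indices(zone)
    rows, sel_serial = resolve_selection(out, selection)

    before = dispersion(out, zone, rows)
    reference = out.intensities[np.ix_(rows, idx)].mean(axis=0)
    shifts: dict[int, int] = {}
    warnings: list[str] = []

    candidates = np.array(sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)))
    for i in rows:
        seg = out.intensities[i, idx]
        sse = np.array([np.sum((_shifted_segment(seg, int(s)) - reference) ** 2)
                        for s in candidates])
        best = int(candidates[int(np.argmin(sse))])
        if abs(best) == max_shift:
            sid = out.sample_table.sample_ids[i]
            warnings.append(f"shift saturated at max_shift for sample {sid!r}; left unchanged")
            shifts[int(i)] = 0
            continue
        shifts[int(i)] = best
        if best:
            out.intensities[i, idx] = _shifted_segment(seg, best)

    after = dispersion(out, zone, rows)
    if after > before:
        warnings.append("alignment increased dispersion; data returned unchanged")
        out = spectrum_set.copy()
        after = before
        shifts = {int(i): 0 for i in rows}

    out.provenance.append(MacroCommand(
        "align_zone_ls",
        {"ppm_min": zone.ppm_min, "ppm_max": zone.ppm_max, "max_shift": max_shift},
        selection=sel_serial if isinstance(sel_serial, tuple) else None))
    report = AlignmentReport(zone, "least_squares", shifts, before, after, warnings)
    return out, report


def _warp_coords(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    w = coeffs[0] + coeffs[1] * x
    if coeffs.size == 3:
        w = w + coeffs[2] * x * x
    return w


def _warped(seg: np.ndarray, coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.interp(np.clip(_warp_coords(coeffs, x), 0, seg.size - 1),
                     x, seg)


def align_zone_ptw(spectrum_set: SpectrumSet, zone: PpmZone,
                   selection=None, degree: int = 1
                   ) -> tuple[SpectrumSet, AlignmentReport]:
    """Parametric time warping of one zone against the mean segment.

    Per spectrum a polynomial warp ``w(x) = a0 + a1*x (+ a2*x^2)`` in point
    coordinates is fitted by deterministic local least squares (identity
    start, iteration cap 200, tolerance 1e-8); the zone is resampled by
    linear interpolation at the warped coordinates.  Works best when every
    spectrum carries the same number of peaks in the zone; when it does not,
    the dispersion guard usually rejects the pass and the data come back
    unchanged with a warning.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    _check_not_excluded(spectrum_set, zone)
    out = spectrum_set.copy()
    idx = out.zone_indices(zone)
    rows, sel_serial = resolve_selection(out, selection)

    before = dispersion(out, zone, rows)
    reference = out.intensities[np.ix_(rows, idx)].mean(axis=0)
    x = np.arange(idx.size, dtype=np.float64)
    coeffs_map: dict[int, list] = {}
    warnings: list[str] = []

    x0 = np.array([0.0, 1.0] + ([0.0] if degree == 2 else []))
    for i in rows:
        seg = out.intensities[i, idx]
        if np.ptp(seg) == 0:  # constant segment: warp is singular
            sid = out.sample_table.sample_ids[i]
            warnings.append(f"flat segment for sample {sid!r}; left unchanged")
            coeffs_map[int(i)] = list(x0)
            continue
        res = least_squares(
            lambda c: _warped(seg, c, x) - reference, x0,
            method="lm", max_nfev=200 * (degree + 2), xtol=1e-8, ftol=1e-8, gtol=1e-8)
        coeffs = res.x
        coeffs_map[int(i)] = [float(c) for c in coeffs]
        out.intensities[i, idx] = _warped(seg, coeffs, x)

    after = dispersion(out, zone, rows)
    if after > before:
        warnings.append("warping increased dispersion; data returned unchanged")
        out = spectrum_set.copy()
        after = before
        coeffs_map = {int(i): list(x0) for i in rows}

    out.provenance.append(MacroCommand(
        "align_zone_ptw",
        {"ppm_min": zone.ppm_min, "ppm_max": zone.ppm_max, "degree": degree},
        selection=sel_serial if isinstance(sel_serial, tuple) else None))
    report = AlignmentReport(zone, "ptw", coeffs_map, before, after, warnings)
    return out, report
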