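"""Baseline handling: global asymmetric-least-squares, local chords, solvent zeroing.

The global method is the two-parameter Whittaker-style asymmetric least
squares smoother: a second-difference penalty controls stiffness, an
asymmetry fraction down-weights points sitting above the running baseline
(peaks) so the fit hugs the signal-free floor.  The local method is the
targeted-metabolomics correction: inside a user zone, subtract the straight
chord joining the zone edges so a quantification zone is not polluted by
the tails of intense neighbours.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .types import MacroCommand, PpmZone, SpectrumSet, resolve_selection

__all__ = ["als_baseline", "global_baseline", "local_baseline", "zero_zones"]


def als_baseline(y: np.ndarray, smoothing: float = 1e6, asymmetry: float = 0.05,
                 max_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate of one spectrum.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + smoothing * sum (d2 z)^2`` with
    weights ``asymmetry`` for positive residuals (candidate peaks) and
    ``1 - asymmetry`` for negative ones, iterated to weight convergence
    (at most ``max_iter`` passes).
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    if not 0 < asymmetry < 1:
        raise ValueError("asymmetry must lie in (0, 1)")
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothing * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        lhs = sparse.diags(w, format="csc") + penalty
        z = spsolve(lhs, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def global_baseline(spectrum_set: SpectrumSet, smoothing: float = 1e6,
                    asymmetry: float = 0.05) -> SpectrumSet:
    """Subtract the ALS baseline from every spectrum; provenance is recorded."""
    out = spectrum_set.copy()
    for i in range(out.n_spectra):
        out.intensities[i] -= als_baseline(out.intensities[i], smoothing, asymmetry)
    out.provenance.append(MacroCommand(
        "global_baseline", {"smoothing": smoothing, "asymmetry": asymmetry}))
    return out


def local_baseline(spectrum_set: SpectrumSet, zone: PpmZone,
                   selection: Optional[Sequence[int]] = None) -> SpectrumSet:
    """Subtract the straight chord joining zone-edge intensities, in-zone only.

    The edge value on each side is the mean of the 3 outermost in-zone
    points; everything outside the zone is untouched bit-for-bit.
    """
    out = spectrum_set.copy()
    idx = out.zone_indices(zone)
    if idx.size < 8:
        raise ValueError(
            f"zone [{zone.ppm_min}, {zone.ppm_max}] has {idx.size} points, needs >= 8")
    rows, sel_serial = resolve_selection(out, selection)
    x = np.arange(idx.size, dtype=np.float64)
    for i in rows:
        seg = out.intensities[i, idx]
        left = seg[:3].mean()
        right = seg[-3:].mean()
        chord = left + (right - left) * x / (idx.size - 1)
        out.intensities[i, idx] = seg - chord
    params = {"ppm_min": zone.ppm_min, "ppm_max": zone.ppm_max}
    if isinstance(sel_serial, list):
        params["rows"] = sel_serial
    out.provenance.append(MacroCommand(
        "local_baseline", params,
        selection=sel_serial if isinstance(sel_serial, tuple) else None))
    return out


def zero_zones(spectrum_set: SpectrumSet, zones: Sequence[PpmZone]) -> SpectrumSet:
    """Zero solvent/contaminant zones and mark them excluded for bucketing."""
    out = spectrum_set.copy()
    for zone in zones:
        mask = zone.mask(out.ppm_axis)
        out.intensities[:, mask] = 0.0
        out.excluded_zones.append(zone)
    out.provenance.append(MacroCommand(
        "zero_zones",
        {"zones": [(z.ppm_min, z.ppm_max) for z in zones]}))
    return out
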