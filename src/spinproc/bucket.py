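"""Bucketing strategies, bucket integration, SNR matrix and bucket filtering.

Three ways to segment the ppm axis into buckets (the variables of the final
data matrix): uniform tiling, adaptive intelligent binning (AIB) — a
recursive, data-driven edge placement that maximizes a bin-quality value so
each bucket captures one resonance pattern — and explicit user-chosen
ranges for targeted work.  Buckets never intersect solvent-excluded zones.

AIB bin value, for a bin b over spectra s:

    V(b) = sum_s [ (Imax_s - Iledge_s) * (Imax_s - Iredge_s) ] ** R

with R in (0, 1] a resolution exponent (default 0.5).  A split of b at an
interior point is accepted iff it maximizes V(left) + V(right) over all
interior points, that sum exceeds V(b), and both children exceed the noise
minimum — the same formula evaluated on a hypothetical noise-only bin whose
maximum is ``noise_floor`` and whose edges are zero, i.e.
``n_spectra * noise_floor ** (2R)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import PpmZone, SpectrumSet

__all__ = [
    "Bucket",
    "BucketTable",
    "uniform_buckets",
    "aib_buckets",
    "manual_buckets",
    "integrate",
    "snr",
    "filter_by_snr",
    "normalize",
    "read_bucket_table",
    "write_bucket_table",
]


@dataclass(frozen=True)
class Bucket:
    ppm_min: float
    ppm_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError(f"bucket requires ppm_min < ppm_max, got [{self.ppm_min}, {self.ppm_max}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_min + self.ppm_max)

    @property
    def width(self) -> float:
        return self.ppm_max - self.ppm_min

    def as_zone(self) -> PpmZone:
        return PpmZone(self.ppm_min, self.ppm_max)


def _default_label(center: float) -> str:
    return f"B{center:.4f}"


class BucketTable:
    """Ordered, non-overlapping buckets, descending by center ppm."""

    def __init__(self, buckets: Sequence[Bucket]):
        labelled = []
        seen: dict[str, int] = {}
        for b in sorted(buckets, key=lambda b: -b.center):
            label = b.label or _default_label(b.center)
            if label in seen:
                seen[label] += 1
                label = f"{label}_{seen[label]}"
            else:
                seen[label] = 1
            labelled.append(Bucket(b.ppm_min, b.ppm_max, label))
        for a, b in zip(labelled, labelled[1:]):
            # descending order: a sits left (higher ppm) of b
            if b.ppm_max > a.ppm_min + 1e-12:
                raise ValueError(
                    f"overlapping buckets: [{a.ppm_min}, {a.ppm_max}] and "
                    f"[{b.ppm_min}, {b.ppm_max}]")
        self.buckets: list[Bucket] = labelled

    def __len__(self) -> int:
        return len(self.buckets)

    def __iter__(self):
        return iter(self.buckets)

    def __getitem__(self, i) -> Bucket:
        return self.buckets[i]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.buckets]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BucketTable) and self.buckets == other.buckets

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels,
             "ppm_min": [b.ppm_min for b in self.buckets],
             "ppm_max": [b.ppm_max for b in self.buckets]})


def write_bucket_table(table: BucketTable, path) -> Path:
    path = Path(path)
    table.frame().to_csv(path, sep="\t", index=False)
    return path


def read_bucket_table(path) -> BucketTable:
    frame = pd.read_csv(path, sep="\t")
    return BucketTable([Bucket(r.ppm_min, r.ppm_max, str(r.label))
                        for r in frame.itertuples()])


# --- excluded-zone handling -------------------------------------------------

def _subtract_exclusions(ppm_min: float, ppm_max: float,
                         exclusions: Sequence[PpmZone]) -> list[tuple[float, float]]:
    """Closed interval minus the union of excluded zones."""
    pieces = [(ppm_min, ppm_max)]
    for ex in exclusions:
        nxt: list[tuple[float, float]] = []
        for lo, hi in pieces:
            if ex.ppm_max <= lo or ex.ppm_min >= hi:
                nxt.append((lo, hi))
                continue
            if ex.ppm_min > lo:
                nxt.append((lo, ex.ppm_min))
            if ex.ppm_max < hi:
                nxt.append((ex.ppm_max, hi))
        pieces = nxt
    return pieces


def _has_point_support(spectrum_set: SpectrumSet, lo: float, hi: float) -> bool:
    ax = spectrum_set.ppm_axis
    return bool(np.any((ax >= lo) & (ax <= hi)))


def check_against_exclusions(spectrum_set: SpectrumSet, table: BucketTable) -> None:
    """Raise if any bucket intersects an excluded zone (all strategies)."""
    for b in table:
        for ex in spectrum_set.excluded_zones:
            if b.as_zone().overlaps(ex):
                raise ValueError(
                    f"bucket {b.label} [{b.ppm_min}, {b.ppm_max}] intersects "
                    f"excluded zone [{ex.ppm_min}, {ex.ppm_max}]")


# --- strategies -------------------------------------------------------------

def uniform_buckets(spectrum_set: SpectrumSet, zone: PpmZone,
                    width_ppm: float) -> BucketTable:
    """Tile a zone with contiguous buckets of fixed width.

    Tiling runs from ``zone.ppm_max`` downward; a narrower final bucket is
    kept only when at least half the nominal width.  Buckets are clipped
    against excluded zones (a straddling bucket is split); clips without
    point support are dropped.
    """
    if width_ppm <= spectrum_set.spacing:
        raise ValueError("bucket width must exceed the axis spacing")
    pieces = _subtract_exclusions(zone.ppm_min, zone.ppm_max, spectrum_set.excluded_zones)
    if not pieces:
        raise ValueError("zone is fully excluded")

    raw: list[tuple[float, float]] = []
    hi = zone.ppm_max
    while hi - zone.ppm_min > 1e-12:
        lo = max(zone.ppm_min, hi - width_ppm)
        if hi - lo >= width_ppm / 2 - 1e-12:
            raw.append((lo, hi))
        hi = lo

    buckets = []
    for lo, hi in raw:
        for plo, phi in _subtract_exclusions(lo, hi, spectrum_set.excluded_zones):
            if phi - plo > 1e-12 and _has_point_support(spectrum_set, plo, phi):
                buckets.append(Bucket(plo, phi))
    if not buckets:
        raise ValueError("no buckets survive exclusion clipping")
    return BucketTable(buckets)


def _aib_value(seg: np.ndarray, lo: int, hi: int, r_exp: float) -> float:
    """V of the bin [lo, hi] (inclusive point indices) over all spectra."""
    window = seg[:, lo:hi + 1]
    imax = window.max(axis=1)
    prod = (imax - seg[:, lo]) * (imax - seg[:, hi])
    return float(np.sum(np.maximum(prod, 0.0) ** r_exp))


def _aib_split(seg: np.ndarray, lo: int, hi: int, r_exp: float,
               v_noise: float, out: list[tuple[int, int]]) -> None:
    parent = _aib_value(seg, lo, hi, r_exp)
    best_sum, best_j = -np.inf, None
    for j in range(lo + 1, hi - 1):          # children [lo..j], [j+1..hi], >= 2 pts each
        v_left = _aib_value(seg, lo, j, r_exp)
        v_right = _aib_value(seg, j + 1, hi, r_exp)
        if v_left + v_right > best_sum:
            best_sum, best_j = v_left + v_right, j
    if best_j is not None and best_sum > parent:
        v_left = _aib_value(seg, lo, best_j, r_exp)
        v_right = _aib_value(seg, best_j + 1, hi, r_exp)
        if v_left > v_noise and v_right > v_noise:
            _aib_split(seg, lo, best_j, r_exp, v_noise, out)
            _aib_split(seg, best_j + 1, hi, r_exp, v_noise, out)
            return
    out.append((lo, hi))


def aib_buckets(spectrum_set: SpectrumSet, zone: PpmZone,
                resolution_exp: float = 0.5,
                noise_floor: float = 0.0) -> BucketTable:
    """Adaptive intelligent binning of one zone.

    Recursively splits the zone wherever splitting raises the total bin
    value, then keeps only leaves whose value exceeds the noise minimum
    (so a pure-noise zone yields no buckets at all).
    """
    if not 0 < resolution_exp <= 1:
        raise ValueError("resolution_exp must lie in (0, 1]")
    for ex in spectrum_set.excluded_zones:
        if zone.overlaps(ex):
            raise ValueError("zone overlaps an excluded zone")
    idx = spectrum_set.zone_indices(zone)
    if idx.size < 3:
        raise ValueError("zone narrower than 3 points")
    seg = spectrum_set.intensities[:, idx]
    v_noise = spectrum_set.n_spectra * float(noise_floor) ** (2 * resolution_exp) \
        if noise_floor > 0 else 0.0

    leaves: list[tuple[int, int]] = []
    _aib_split(seg, 0, idx.size - 1, resolution_exp, v_noise, leaves)
    leaves.sort()

    ax = spectrum_set.ppm_axis
    buckets = []
    for lo, hi in leaves:
        if _aib_value(seg, lo, hi, resolution_exp) > v_noise:
            buckets.append(Bucket(float(ax[idx[hi]]), float(ax[idx[lo]])))
    return BucketTable(buckets)


def manual_buckets(ranges: Sequence[tuple[float, float]]) -> BucketTable:
    """Explicit ppm ranges, validated for overlap, sorted descending."""
    buckets = [Bucket(lo, hi) for lo, hi in ranges]
    ordered = sorted(buckets, key=lambda b: -b.center)
    for a, b in zip(ordered, ordered[1:]):
        if b.ppm_max > a.ppm_min + 1e-12:
            raise ValueError(
                f"overlapping ranges: [{a.ppm_min}, {a.ppm_max}] and "
                f"[{b.ppm_min}, {b.ppm_max}]")
    return BucketTable(ordered)


# --- integration, SNR, filtering -------------------------------------------

def integrate(spectrum_set: SpectrumSet, table: BucketTable,
              method: str = "sum") -> pd.DataFrame:
    """Bucket integrals: N x B DataFrame, sample_id rows, bucket-label columns.

    ``sum`` multiplies the in-bucket intensity sum by the axis spacing;
    ``trapezoid`` applies the trapezoidal rule on the in-bucket grid.
    """
    if method not in ("sum", "trapezoid"):
        raise ValueError(f"unknown integration method {method!r}")
    check_against_exclusions(spectrum_set, table)
    dx = spectrum_set.spacing
    cols = {}
    for b in table:
        idx = spectrum_set.zone_indices(b.as_zone())
        seg = spectrum_set.intensities[:, idx]
        if method == "sum":
            cols[b.label] = seg.sum(axis=1) * dx
        else:
            # descending ppm axis: reverse so x increases
            cols[b.label] = np.trapezoid(seg[:, ::-1],
                                         spectrum_set.ppm_axis[idx][::-1], axis=1)
    return pd.DataFrame(cols, index=pd.Index(spectrum_set.sample_table.sample_ids,
                                             name="sample_id"))


def snr(spectrum_set: SpectrumSet, table: BucketTable,
        noise_zone: PpmZone) -> pd.DataFrame:
    """Signal-to-noise matrix: per-bucket max over twice the noise SD.

    Noise SD per spectrum is the standard deviation of the noise zone after
    removing its linear trend (the zone must be signal-free and hold at
    least 32 points).  ``SNR = max(in-bucket intensity, 0) / (2 * sd)``.
    """
    nidx = spectrum_set.zone_indices(noise_zone)
    if nidx.size < 32:
        raise ValueError(f"noise zone needs >= 32 points, has {nidx.size}")
    x = np.arange(nidx.size, dtype=np.float64)
    sds = np.empty(spectrum_set.n_spectra)
    for i in range(spectrum_set.n_spectra):
        seg = spectrum_set.intensities[i, nidx]
        coef = np.polynomial.polynomial.polyfit(x, seg, 1)
        resid = seg - np.polynomial.polynomial.polyval(x, coef)
        sds[i] = resid.std()
    if np.any(sds == 0):
        bad = [spectrum_set.sample_table.sample_ids[i]
               for i in np.nonzero(sds == 0)[0]]
        raise ValueError(f"degenerate noise zone (sd = 0) for samples {bad}")

    cols = {}
    for b in table:
        idx = spectrum_set.zone_indices(b.as_zone())
        peak = spectrum_set.intensities[:, idx].max(axis=1)
        cols[b.label] = np.maximum(peak, 0.0) / (2.0 * sds)
    return pd.DataFrame(cols, index=pd.Index(spectrum_set.sample_table.sample_ids,
                                             name="sample_id"))


def filter_by_snr(data_matrix: pd.DataFrame, snr_matrix: pd.DataFrame,
                  table: BucketTable, threshold: float,
                  min_fraction: float = 0.5) -> tuple[pd.DataFrame, BucketTable]:
    """Drop buckets whose SNR clears ``threshold`` in too few spectra.

    A bucket survives iff the fraction of spectra with ``SNR >= threshold``
    is at least ``min_fraction``.  Column-wise only: no spectrum is removed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = (snr_matrix >= threshold).mean(axis=0)
    keep = [lab for lab in data_matrix.columns if frac[lab] >= min_fraction]
    kept_table = BucketTable([b for b in table if b.label in set(keep)])
    return data_matrix[keep], kept_table


def normalize(data_matrix: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Row normalization: ``none`` or ``constant_sum`` (rows scaled to 100)."""
    if method == "none":
        return data_matrix.copy()
    if method != "constant_sum":
        raise ValueError(f"unknown normalization {method!r}")
    sums = data_matrix.sum(axis=1)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"nonpositive row sums for samples {bad}")
    return data_matrix.div(sums, axis=0) * 100.0
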