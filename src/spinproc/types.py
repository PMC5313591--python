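"""Core in-memory containers shared by every processing stage.

The central object is :class:`SpectrumSet`: an N x P matrix of real spectra
sharing one strictly decreasing ppm axis, carrying per-spectrum sample
metadata (experimental factor levels) and a provenance list of every
processing command applied so far.  All zone-wise operations act on closed
ppm intervals (:class:`PpmZone`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "AxisSpec",
    "FidRecord",
    "PpmZone",
    "SampleTable",
    "SpectrumSet",
    "MacroCommand",
]


@dataclass(frozen=True)
class AxisSpec:
    """Spectral-axis definition: frequency, width, grid size and ppm limits.

    The ppm axis is uniform and strictly decreasing (conventional NMR display
    orientation): point ``k`` sits at ``ppm_max - k * sw_ppm / (n_points - 1)``,
    so index 0 is the highest chemical shift.
    """

    sfo_mhz: float
    sw_ppm: float
    n_points: int
    ppm_max: float

    def __post_init__(self) -> None:
        if self.sfo_mhz <= 0:
            raise ValueError("sfo_mhz must be positive")
        if self.sw_ppm <= 0:
            raise ValueError("sw_ppm must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def ppm_min(self) -> float:
        return self.ppm_max - self.sw_ppm

    @property
    def spacing(self) -> float:
        """Axis spacing in ppm (positive)."""
        return self.sw_ppm / (self.n_points - 1)

    @property
    def sw_hz(self) -> float:
        return self.sw_ppm * self.sfo_mhz

    @property
    def dwell_s(self) -> float:
        """Dwell time implied by the spectral width, in seconds."""
        return 1.0 / self.sw_hz

    @property
    def carrier_ppm(self) -> float:
        """Carrier position = center of the spectral window."""
        return self.ppm_max - self.sw_ppm / 2.0

    def ppm_axis(self) -> np.ndarray:
        return self.ppm_max - np.arange(self.n_points) * self.spacing

    def index_of(self, ppm: float) -> int:
        """Index of the axis point nearest ``ppm``."""
        k = int(round((self.ppm_max - ppm) / self.spacing))
        return min(max(k, 0), self.n_points - 1)


@dataclass
class FidRecord:
    """One complex free-induction decay with its acquisition parameters."""

    signal: np.ndarray          # complex, length TD/2
    dwell_us: float             # sampling interval, microseconds
    sfo_mhz: float              # spectrometer frequency, MHz
    sw_ppm: float               # spectral width, ppm
    o1_hz: float                # carrier offset from 0 ppm, Hz
    group_delay: float = 0.0    # digital-filter delay, points (may be fractional)
    vendor: str = "bruker"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.complex128)
        if self.signal.size < 2:
            raise ValueError("FID must contain at least 2 complex points")
        if self.sw_ppm <= 0 or self.sfo_mhz <= 0:
            raise ValueError("sw_ppm and sfo_mhz must be positive")

    @property
    def carrier_ppm(self) -> float:
        return self.o1_hz / self.sfo_mhz


@dataclass(frozen=True)
class PpmZone:
    """Closed chemical-shift interval [ppm_min, ppm_max]."""

    ppm_min: float
    ppm_max: float

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError(
                f"PpmZone requires ppm_min < ppm_max, got [{self.ppm_min}, {self.ppm_max}]"
            )

    @property
    def width(self) -> float:
        return self.ppm_max - self.ppm_min

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_min + self.ppm_max)

    def mask(self, ppm_axis: np.ndarray) -> np.ndarray:
        """Boolean membership: ppm_min <= ppm[k] <= ppm_max (closed interval)."""
        return (ppm_axis >= self.ppm_min) & (ppm_axis <= self.ppm_max)

    def overlaps(self, other: "PpmZone") -> bool:
        return self.ppm_min <= other.ppm_max and other.ppm_min <= self.ppm_max


class SampleTable:
    """Per-spectrum metadata: sample_id plus ordered factor columns."""

    def __init__(self, frame: pd.DataFrame):
        if "sample_id" not in frame.columns:
            raise ValueError("sample table requires a 'sample_id' column")
        if frame.shape[1] < 2:
            raise ValueError("sample table requires at least one factor column")
        ids = frame["sample_id"].astype(str)
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample_id values: {dups}")
        frame = frame.copy()
        frame["sample_id"] = ids
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def factor_names(self) -> list[str]:
        return [c for c in self.frame.columns if c != "sample_id"]

    def levels(self, factor: str) -> list[str]:
        if factor not in self.factor_names:
            raise KeyError(f"unknown factor {factor!r}; have {self.factor_names}")
        return sorted(self.frame[factor].astype(str).unique())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleTable) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class MacroCommand:
    """One recorded processing step: op name, serialized params, optional subset."""

    op_name: str
    params: dict = field(default_factory=dict)
    selection: Optional[tuple[str, str]] = None  # (factor, level)


@dataclass
class SpectrumSet:
    """Aligned-grid matrix of N real spectra x P points with shared ppm axis.

    ``excluded_zones`` records solvent/contaminant regions zeroed by
    :func:`spinproc.baseline.zero_zones`; bucketing strategies never emit a
    bucket intersecting them.
    """

    intensities: np.ndarray      # N x P, float64
    ppm_axis: np.ndarray         # length P, strictly decreasing
    sample_table: SampleTable
    provenance: list[MacroCommand] = field(default_factory=list)
    excluded_zones: list[PpmZone] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if self.ppm_axis.shape != (p,):
            raise ValueError("ppm_axis length must match the number of points")
        if not np.all(np.diff(self.ppm_axis) < 0):
            raise ValueError("ppm_axis must be strictly decreasing")
        if len(self.sample_table) != n:
            raise ValueError(
                f"sample table has {len(self.sample_table)} rows for {n} spectra"
            )

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def spacing(self) -> float:
        return float(self.ppm_axis[0] - self.ppm_axis[1])

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            intensities=self.intensities.copy(),
            ppm_axis=self.ppm_axis.copy(),
            sample_table=SampleTable(self.sample_table.frame.copy()),
            provenance=list(self.provenance),
            excluded_zones=list(self.excluded_zones),
        )

    def zone_indices(self, zone: PpmZone) -> np.ndarray:
        """Sorted point indices belonging to a closed ppm zone."""
        idx = np.nonzero(zone.mask(self.ppm_axis))[0]
        if idx.size == 0:
            raise ValueError(f"zone [{zone.ppm_min}, {zone.ppm_max}] contains no axis points")
        return idx

    def index_of(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.ppm_axis - ppm)))


def resolve_selection(spectrum_set: SpectrumSet, selection) -> tuple[np.ndarray, object]:
    """Normalize a row selection to indices plus a replayable serialized form.

    ``selection`` may be None (all rows), a ``(factor, level)`` pair, or an
    explicit index sequence.  Returns ``(indices, serializable)`` where the
    serialized form goes into provenance so a macro replay resolves the same
    rows on the same input.
    """
    if selection is None:
        return np.arange(spectrum_set.n_spectra), None
    if (isinstance(selection, tuple) and len(selection) == 2
            and all(isinstance(s, str) for s in selection)):
        factor, level = selection
        table = spectrum_set.sample_table
        if factor not in table.factor_names:
            raise KeyError(f"unknown factor {factor!r}; have {table.factor_names}")
        col = table.frame[factor].astype(str)
        if level not in set(col):
            raise KeyError(f"level {level!r} absent from factor {factor!r}")
        return np.nonzero((col == level).to_numpy())[0], (factor, level)
    idx = np.asarray(list(selection), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= spectrum_set.n_spectra):
        raise IndexError("selection index out of range")
    return idx, [int(i) for i in idx]
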