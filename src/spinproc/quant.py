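"""qHNMR quantification and the spreadsheet / matrix exports.

Quantification is the standard internal-reference proportionality: with
``A(s, b)`` the bucket integral of spectrum ``s`` in bucket ``b`` and
``nH_b`` the proton count behind the bucket,

    conc(s, b) = C_ref * (A(s, b) / nH_b) / (A(s, ref) / nH_ref)

The targeted-metabolomics workbook aggregates five linked tables (samples,
buckets, snr, data_matrix, quantifications) into one XLSX file; the
fingerprinting branch exports plain TSV matrices directly ingestible by
downstream statistics tools.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .bucket import BucketTable
from .types import SampleTable, SpectrumSet

__all__ = [
    "QuantSpec",
    "quantify",
    "export_qhnmr",
    "read_qhnmr",
    "export_matrix",
]

QUANT_FORMULA = "conc(s,b) = C_ref * (A(s,b)/nH_b) / (A(s,ref)/nH_ref)"

SHEETS = ("samples", "buckets", "snr", "data_matrix", "quantifications")


@dataclass
class QuantSpec:
    """Proton counts and the internal reference for qHNMR quantification."""

    proton_counts: dict[str, int]          # bucket label -> nH (>= 1)
    ref_bucket: str                        # label of the internal standard
    ref_concentration: float               # e.g. mM
    ref_proton_count: int = 1
    metabolites: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_proton_count < 1:
            raise ValueError("ref_proton_count must be >= 1")
        if any(n < 1 for n in self.proton_counts.values()):
            raise ValueError("all proton counts must be >= 1")
        if self.ref_concentration <= 0:
            raise ValueError("ref_concentration must be > 0")


def quantify(data_matrix: pd.DataFrame, qs: QuantSpec) -> pd.DataFrame:
    """Concentrations per spectrum per bucket against the internal reference."""
    if qs.ref_bucket not in data_matrix.columns:
        raise KeyError(f"reference bucket {qs.ref_bucket!r} absent from data matrix")
    ref = data_matrix[qs.ref_bucket]
    if (ref <= 0).any():
        bad = list(ref.index[ref <= 0])
        raise ValueError(f"nonpositive reference integral for samples {bad}")
    ref_molar = ref / qs.ref_proton_count
    out = {}
    for label in data_matrix.columns:
        n_h = qs.proton_counts.get(label, 1)
        out[label] = qs.ref_concentration * (data_matrix[label] / n_h) / ref_molar
    return pd.DataFrame(out, index=data_matrix.index)


def _bucket_sheet(table: BucketTable, qs: Optional[QuantSpec]) -> pd.DataFrame:
    frame = table.frame()
    frame["proton_count"] = [
        (qs.proton_counts.get(b.label, 1) if qs else 1) for b in table]
    frame["metabolite"] = [
        (qs.metabolites.get(b.label, "") if qs else "") for b in table]
    return frame


def export_qhnmr(spectrum_set: SpectrumSet, table: BucketTable,
                 data_matrix: pd.DataFrame, snr_matrix: pd.DataFrame,
                 qs: Optional[QuantSpec], path) -> Path:
    """Write the five-sheet qHNMR workbook.

    Sheets: samples, buckets, snr, data_matrix, quantifications.  With no
    QuantSpec the quantifications sheet is left empty and a warning is
    issued.  The quantification formula is stored in the workbook's
    description property for transparency.
    """
    path = Path(path)
    labels = list(table.labels)
    for frame, name in ((data_matrix, "data_matrix"), (snr_matrix, "snr")):
        if list(frame.columns) != labels:
            raise ValueError(f"{name} columns do not match the bucket table")
        if list(frame.index) != spectrum_set.sample_table.sample_ids:
            raise ValueError(f"{name} rows do not match the sample table")

    if qs is not None:
        quants = quantify(data_matrix, qs)
    else:
        _warnings.warn("no QuantSpec given; quantifications sheet left empty")
        quants = pd.DataFrame(index=data_matrix.index)

    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        spectrum_set.sample_table.frame.to_excel(writer, sheet_name="samples", index=False)
        _bucket_sheet(table, qs).to_excel(writer, sheet_name="buckets", index=False)
        snr_matrix.to_excel(writer, sheet_name="snr")
        data_matrix.to_excel(writer, sheet_name="data_matrix")
        quants.to_excel(writer, sheet_name="quantifications")
        writer.book.properties.description = QUANT_FORMULA
    return path


def read_qhnmr(path) -> dict[str, pd.DataFrame]:
    """Read the five workbook sheets back into DataFrames (keyed by sheet name)."""
    path = Path(path)
    out = {}
    for name in SHEETS:
        matrix = name in ("snr", "data_matrix", "quantifications")
        frame = pd.read_excel(path, sheet_name=name,
                              index_col=0 if matrix else None)
        if matrix:
            frame = frame.astype(np.float64)
            frame.index = frame.index.astype(str)
        out[name] = frame
    return out


def export_matrix(data_matrix: pd.DataFrame, snr_matrix: Optional[pd.DataFrame],
                  sample_table: SampleTable, out_dir,
                  flavor: str = "generic_tsv") -> list[Path]:
    """Write statistics-ready matrices.

    ``generic_tsv``: data matrix TSV (rows samples, columns buckets) plus a
    companion sample-factor TSV (and the SNR matrix when given).
    ``metaboanalyst``: one table with sample names in column 1, the first
    factor as class label in column 2, bucket columns after — the layout
    that tool ingests directly.
    """
    if data_matrix.shape[1] == 0:
        raise ValueError("no buckets to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if flavor == "generic_tsv":
        p = out_dir / "data_matrix.tsv"
        data_matrix.to_csv(p, sep="\t", float_format="%.17g")  # exact round trip
        written.append(p)
        p = out_dir / "samples.tsv"
        sample_table.frame.to_csv(p, sep="\t", index=False)
        written.append(p)
        if snr_matrix is not None:
            p = out_dir / "snr_matrix.tsv"
            snr_matrix.to_csv(p, sep="\t", float_format="%.17g")
            written.append(p)
    elif flavor == "metaboanalyst":
        first_factor = sample_table.factor_names[0]
        frame = data_matrix.copy()
        frame.insert(0, "Label", sample_table.frame.set_index("sample_id")
                     .loc[frame.index, first_factor].to_numpy())
        frame.index.name = "Sample"
        p = out_dir / "metaboanalyst.tsv"
        frame.to_csv(p, sep="\t")
        written.append(p)
    else:
        raise ValueError(f"unknown export flavor {flavor!r}")
    return written
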