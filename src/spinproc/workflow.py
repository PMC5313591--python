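"""Recordable macro workflows and batch replay.

Every processing operation appends a :class:`MacroCommand` to the spectra
set's provenance; serializing that list gives a line-oriented, diff-able
standard-operating-procedure file which :func:`replay` re-executes on a new
raw batch.  The macro grammar is one command per line::

    # spinproc macro v1
    process lb=0.3 autophase=true
    calibrate ppm_min=-0.1000 ppm_max=0.1000 ref_ppm=0.0000
    align_zone_ls ppm_min=1.1000 ppm_max=1.4000 max_shift=20 @group=A
    uniform_buckets ppm_min=0.5000 ppm_max=4.0000 width_ppm=0.0400
    integrate method=sum
    snr ppm_min=9.0000 ppm_max=9.8000
    filter_by_snr threshold=3.0 min_fraction=0.5
    export flavor=generic_tsv

``@factor=level`` restricts an operation to the samples at one factor
level.  ppm parameters are written with 4 decimals (kept exact whenever
rounding is lossless, so serialize/parse is an identity on commands built
from 4-decimal zones).
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional

from . import baseline as _baseline
from . import align as _align
from . import bucket as _bucket
from . import quant as _quant
from .fidproc import ProcessingParams, process_fid
from .types import MacroCommand, PpmZone, SpectrumSet
from .vendor_io import (FormatError, assemble_spectrum_set, read_bruker_fid,
                        read_nmrml, read_sample_table, read_varian_fid)

__all__ = [
    "MACRO_HEADER",
    "ReplayError",
    "record",
    "serialize_macro",
    "parse_macro",
    "write_macro",
    "read_macro",
    "load_raw_batch",
    "apply_command",
    "replay",
]

MACRO_HEADER = "# spinproc macro v1"
log = logging.getLogger("spinproc")

_PAIR_KEYS = {"zones", "ranges"}
_INTLIST_KEYS = {"rows"}
_PPM_DECIMALS = 4


class ReplayError(RuntimeError):
    """A macro step failed; carries the 0-based command index."""

    def __init__(self, index: int, command: MacroCommand, cause: Exception):
        super().__init__(f"command {index} ({command.op_name}) failed: {cause}")
        self.index = index
        self.command = command
        self.cause = cause


# --- serialization ---------------------------------------------------------

def _fmt_float(key: str, v: float) -> str:
    if "ppm" in key:
        rounded = f"{v:.{_PPM_DECIMALS}f}"
        if float(rounded) == v:
            return rounded
    return repr(float(v))


def _fmt_value(key: str, v) -> str:
    if key in _PAIR_KEYS:
        return ";".join(f"{_fmt_float('ppm', a)}:{_fmt_float('ppm', b)}" for a, b in v)
    if key in _INTLIST_KEYS:
        return ",".join(str(int(i)) for i in v)
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        return _fmt_float(key, v)
    return str(v)


def _parse_value(key: str, s: str):
    if key in _PAIR_KEYS:
        if not s:
            return []
        return [tuple(float(x) for x in pair.split(":")) for pair in s.split(";")]
    if key in _INTLIST_KEYS:
        return [int(x) for x in s.split(",")] if s else []
    if s in ("true", "false"):
        return s == "true"
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def serialize_macro(commands: list[MacroCommand]) -> str:
    lines = [MACRO_HEADER]
    for cmd in commands:
        parts = [cmd.op_name]
        for key, value in cmd.params.items():
            parts.append(f"{key}={_fmt_value(key, value)}")
        if cmd.selection is not None:
            factor, level = cmd.selection
            parts.append(f"@{factor}={level}")
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


def parse_macro(text: str) -> list[MacroCommand]:
    commands = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        op_name, params, selection = tokens[0], {}, None
        for tok in tokens[1:]:
            if tok.startswith("@"):
                factor, _, level = tok[1:].partition("=")
                selection = (factor, level)
                continue
            key, _, value = tok.partition("=")
            params[key] = _parse_value(key, value)
        commands.append(MacroCommand(op_name, params, selection))
    return commands


def write_macro(commands: list[MacroCommand], path) -> Path:
    path = Path(path)
    path.write_text(serialize_macro(commands), encoding="utf-8")
    return path


def read_macro(path) -> list[MacroCommand]:
    return parse_macro(Path(path).read_text(encoding="utf-8"))


# --- command application ---------------------------------------------------

def _zone(params: dict) -> PpmZone:
    return PpmZone(params["ppm_min"], params["ppm_max"])


def _selection_of(cmd: MacroCommand):
    if cmd.selection is not None:
        return cmd.selection
    if "rows" in cmd.params:
        return cmd.params["rows"]
    return None


_SET_OPS = {
    "global_baseline", "local_baseline", "zero_zones",
    "calibrate", "align_zone_ls", "align_zone_ptw",
}


def record(spectrum_set: SpectrumSet, command: MacroCommand) -> SpectrumSet:
    """Apply one spectra-set command; provenance grows by exactly one entry."""
    state = {"set": spectrum_set}
    if command.op_name not in _SET_OPS:
        raise ValueError(f"unknown or non-set op {command.op_name!r}")
    apply_command(state, command)
    return state["set"]


def apply_command(state: dict, cmd: MacroCommand) -> None:
    """Execute one macro command against the pipeline state in place.

    ``state`` keys: ``set`` (SpectrumSet), then as the pipeline advances
    ``buckets``, ``data_matrix``, ``snr_matrix``, ``reports``, ``exports``.
    """
    op = cmd.op_name
    p = cmd.params
    sel = _selection_of(cmd)

    if op == "process":
        return  # consumed at load time by replay()
    if op == "global_baseline":
        state["set"] = _baseline.global_baseline(
            state["set"], p.get("smoothing", 1e6), p.get("asymmetry", 0.05))
    elif op == "local_baseline":
        state["set"] = _baseline.local_baseline(state["set"], _zone(p), sel)
    elif op == "zero_zones":
        zones = [PpmZone(a, b) for a, b in p.get("zones", [])]
        state["set"] = _baseline.zero_zones(state["set"], zones)
    elif op == "calibrate":
        state["set"] = _align.calibrate(state["set"], _zone(p), p["ref_ppm"])
    elif op == "align_zone_ls":
        state["set"], report = _align.align_zone_ls(
            state["set"], _zone(p), sel, p.get("max_shift", 20))
        state.setdefault("reports", []).append(report)
    elif op == "align_zone_ptw":
        state["set"], report = _align.align_zone_ptw(
            state["set"], _zone(p), sel, p.get("degree", 1))
        state.setdefault("reports", []).append(report)
    elif op == "uniform_buckets":
        state["buckets"] = _bucket.uniform_buckets(
            state["set"], _zone(p), p["width_ppm"])
    elif op == "aib_buckets":
        state["buckets"] = _bucket.aib_buckets(
            state["set"], _zone(p),
            p.get("resolution_exp", 0.5), p.get("noise_floor", 0.0))
    elif op == "manual_buckets":
        state["buckets"] = _bucket.manual_buckets(p["ranges"])
    elif op == "integrate":
        state["data_matrix"] = _bucket.integrate(
            state["set"], state["buckets"], p.get("method", "sum"))
    elif op == "snr":
        state["snr_matrix"] = _bucket.snr(state["set"], state["buckets"], _zone(p))
    elif op == "filter_by_snr":
        state["data_matrix"], state["buckets"] = _bucket.filter_by_snr(
            state["data_matrix"], state["snr_matrix"], state["buckets"],
            p["threshold"], p.get("min_fraction", 0.5))
        state["snr_matrix"] = state["snr_matrix"][state["data_matrix"].columns]
    elif op == "normalize":
        state["data_matrix"] = _bucket.normalize(
            state["data_matrix"], p.get("method", "constant_sum"))
    elif op == "export":
        out_dir = state.get("out_dir", ".")
        written = _quant.export_matrix(
            state["data_matrix"], state.get("snr_matrix"),
            state["set"].sample_table, out_dir, p.get("flavor", "generic_tsv"))
        state.setdefault("exports", []).extend(written)
    else:
        raise ValueError(f"unknown op {op!r}")


# --- batch loading and replay ----------------------------------------------

def _processing_from_macro(commands: list[MacroCommand]) -> ProcessingParams:
    for cmd in commands:
        if cmd.op_name == "process":
            p = cmd.params
            return ProcessingParams(
                zero_fill_to=p.get("zero_fill_to"),
                line_broadening_hz=p.get("lb", 0.3),
                phase0_deg=p.get("phase0", 0.0),
                phase1_deg=p.get("phase1", 0.0),
                autophase=p.get("autophase", True),
            )
    return ProcessingParams()


def load_raw_batch(raw_dir, params: ProcessingParams = ProcessingParams()) -> SpectrumSet:
    """Read a raw batch directory into a processed SpectrumSet.

    Layout: one vendor directory per sample (Bruker when it holds ``acqus``,
    Varian when ``procpar``, else a ``*.nmrml`` file of the sample's name)
    plus a ``samples.tsv`` metadata table naming every sample directory.
    """
    raw_dir = Path(raw_dir)
    table = read_sample_table(raw_dir / "samples.tsv")
    spectra = []
    for sid in table.sample_ids:
        sub = raw_dir / sid
        if (sub / "acqus").is_file():
            fid = read_bruker_fid(sub)
        elif (sub / "procpar").is_file():
            fid = read_varian_fid(sub)
        elif (raw_dir / f"{sid}.nmrml").is_file():
            fid = read_nmrml(raw_dir / f"{sid}.nmrml")
        else:
            raise FormatError(f"no vendor data found for sample {sid!r} under {raw_dir}")
        spectrum, ppm = process_fid(fid, params)
        spectra.append((sid, spectrum, ppm))
    return assemble_spectrum_set(spectra, table)


def replay(macro_file, raw_input_dir, out_dir=".",
           params: Optional[ProcessingParams] = None) -> dict:
    """Re-execute a recorded macro on a raw batch; returns the final state.

    Each step is logged with parameters and duration; any failure raises
    :class:`ReplayError` carrying the 0-based index of the offending
    command.  Output files (from ``export`` commands) land in ``out_dir``.
    """
    commands = read_macro(macro_file)
    if params is None:
        params = _processing_from_macro(commands)
    t0 = time.perf_counter()
    spectrum_set = load_raw_batch(raw_input_dir, params)
    log.info("loaded %d spectra from %s in %.2fs",
             spectrum_set.n_spectra, raw_input_dir, time.perf_counter() - t0)

    state: dict = {"set": spectrum_set, "out_dir": Path(out_dir)}
    for i, cmd in enumerate(commands):
        t0 = time.perf_counter()
        try:
            apply_command(state, cmd)
        except Exception as exc:
            log.error("command %d (%s) failed: %s", i, cmd.op_name, exc)
            raise ReplayError(i, cmd, exc) from exc
        log.info("step %d %s %s (%.3fs)", i, cmd.op_name, cmd.params,
                 time.perf_counter() - t0)
    return state
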