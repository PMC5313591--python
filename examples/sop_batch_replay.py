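"""Expert-mode to batch-mode: record a macro once, replay it on new data.

A processing workflow is serialized as a plain-text macro (the SOP), then
replayed unattended on a second acquisition batch written in the Bruker
directory layout.  The same file drives the ``spinproc process`` CLI verb.
"""

import tempfile
from pathlib import Path

from spinproc import (AxisSpec, MacroCommand, PeakSpec, SimulationPlan,
                      replay, serialize_macro, write_macro, write_raw_batch)

axis = AxisSpec(sfo_mhz=500.0, sw_ppm=12.0, n_points=4096, ppm_max=10.0)


def batch_plan(seed):
    return SimulationPlan(
        n_samples=3,
        peaks=(PeakSpec(0.0, 5e5, 3.0), PeakSpec(2.5, 3e5, 3.0),
               PeakSpec(5.2, 2e5, 4.0)),
        ppm_jitter_sd=0.002, seed=seed)


commands = [
    MacroCommand("process", {"lb": 0.3, "autophase": False}),
    MacroCommand("calibrate", {"ppm_min": -0.2, "ppm_max": 0.2, "ref_ppm": 0.0}),
    MacroCommand("align_zone_ls", {"ppm_min": 2.3, "ppm_max": 2.7, "max_shift": 10}),
    MacroCommand("uniform_buckets", {"ppm_min": 1.0, "ppm_max": 6.0,
                                     "width_ppm": 0.1}),
    MacroCommand("integrate", {"method": "sum"}),
    MacroCommand("snr", {"ppm_min": 7.5, "ppm_max": 9.0}),
    MacroCommand("export", {"flavor": "generic_tsv"}),
]
print("the SOP as stored on disk:")
print(serialize_macro(commands))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_macro(commands, tmp / "sop.macro")
    for batch, seed in (("batch1", 101), ("batch2", 202)):
        raw = write_raw_batch(batch_plan(seed), axis, tmp / batch)
        state = replay(tmp / "sop.macro", raw, tmp / f"out_{batch}")
        dm = state["data_matrix"]
        print(f"{batch}: {dm.shape[0]} spectra x {dm.shape[1]} buckets, "
              f"exports: {[p.name for p in state['exports']]}")
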