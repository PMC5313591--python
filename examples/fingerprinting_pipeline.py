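"""Metabolic-fingerprinting route: FIDs -> aligned spectra -> bucket matrix.

Builds a small synthetic cohort with two factor levels (a treated group has
one doubled resonance), runs baseline correction, calibration and zone
alignment, tiles a region into uniform buckets, filters them by SNR and
prints the per-group bucket means that the downstream statistics would see.
"""

import numpy as np

from spinproc import (AxisSpec, PeakSpec, PpmZone, SimulationPlan,
                      align_zone_ls, calibrate, filter_by_snr,
                      global_baseline, integrate, simulate_spectrum_set, snr,
                      subset_by_factor, uniform_buckets)

axis = AxisSpec(sfo_mhz=500.0, sw_ppm=12.0, n_points=8192, ppm_max=10.0)
assignment = {f"S{i:02d}": ("control" if i < 3 else "treated") for i in range(6)}
plan = SimulationPlan(
    n_samples=6,
    peaks=(
        PeakSpec(0.0, 120.0, 3.0),                      # TSP reference
        PeakSpec(1.33, 80.0, 3.0, multiplicity=2, j_hz=7.0),
        PeakSpec(2.55, 60.0, 3.0, multiplicity=3, j_hz=7.0),
        PeakSpec(5.23, 50.0, 4.0),
    ),
    ppm_jitter_sd=0.002,
    baseline_coeffs=(4.0, -2.0, 3.0),
    noise_sd=0.4,
    factor_assignment=assignment,
    group_effects={("treated", 3): 2.0},               # peak 5.23 doubled
    seed=11,
)
sset = simulate_spectrum_set(plan, axis)

sset = global_baseline(sset)                           # remove the drift
sset = calibrate(sset, PpmZone(-0.2, 0.2), 0.0)        # TSP to 0 ppm
sset, report = align_zone_ls(sset, PpmZone(1.1, 1.6), max_shift=8)
print(f"alignment dispersion: {report.dispersion_before:.3f} -> "
      f"{report.dispersion_after:.3f} (lower = tighter peak overlay)")

buckets = uniform_buckets(sset, PpmZone(0.8, 6.0), width_ppm=0.04)
dm = integrate(sset, buckets)
sm = snr(sset, buckets, PpmZone(8.5, 9.5))
dm, kept = filter_by_snr(dm, sm, buckets, threshold=3.0, min_fraction=0.5)
print(f"buckets: {len(buckets)} tiled, {len(kept)} kept after SNR >= 3 filter")

control = subset_by_factor(sset, "group", "control")
treated = subset_by_factor(sset, "group", "treated")
ratios = dm.iloc[treated].mean() / dm.iloc[control].mean()
top = ratios.sort_values(ascending=False).head(3)
print("top treated/control bucket ratios (the planted effect sits at 5.23 ppm):")
for label, r in top.items():
    print(f"  {label}: {r:.2f}")
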