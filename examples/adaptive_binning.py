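"""Adaptive intelligent binning vs uniform tiling on shifting peaks.

Two close singlets whose positions jitter between samples: fixed-width
tiles cut through peaks, while AIB places a single edge in the inter-peak
valley so each bucket captures one whole resonance.
"""

import numpy as np

from spinproc import (AxisSpec, PeakSpec, PpmZone, SimulationPlan,
                      aib_buckets, integrate, simulate_spectrum_set,
                      uniform_buckets)

axis = AxisSpec(sfo_mhz=500.0, sw_ppm=12.0, n_points=8192, ppm_max=10.0)
plan = SimulationPlan(
    n_samples=5,
    peaks=(PeakSpec(5.2, 80.0, 10.0), PeakSpec(4.8, 60.0, 10.0)),
    ppm_jitter_sd=0.003,
    noise_sd=0.3,
    seed=9,
)
sset = simulate_spectrum_set(plan, axis)
zone = PpmZone(4.5, 5.5)

adaptive = aib_buckets(sset, zone, resolution_exp=0.5, noise_floor=1.0)
uniform = uniform_buckets(sset, zone, width_ppm=0.1)

print(f"uniform tiling: {len(uniform)} buckets of 0.10 ppm")
print(f"adaptive binning: {len(adaptive)} buckets at "
      + ", ".join(f"[{b.ppm_min:.3f}, {b.ppm_max:.3f}]" for b in adaptive))

# spread of each bucket integral across samples: AIB buckets absorb the
# jitter, uniform tiles leak intensity between neighbours
cv = lambda frame: (frame.std() / frame.mean() * 100)
cv_adaptive = cv(integrate(sset, adaptive)).max()
cv_uniform = cv(integrate(sset, uniform)).sort_values().tail(3).mean()
print(f"worst integral CV: adaptive {cv_adaptive:.1f}% vs "
      f"uniform (3 worst tiles) {cv_uniform:.1f}%  (lower = more reproducible)")
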