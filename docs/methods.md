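# Methods

This note records the models, conventions and numerical choices behind
spinproc, and what the synthetic test conditions do and do not establish
about real data.

## Conventions

* **ppm axis.** Uniform, strictly decreasing (index 0 = highest shift).
  Spacing is `SW/(P−1)` with the first point at the highest ppm — the
  Bruker `procs` reading (`OFFSET`, `SW_p/SF`, `SI`). The FFT route
  produces a grid of spacing `SW/P` (carrier at the window center); the
  two conventions differ by less than one part in P and all zone
  arithmetic goes through the actual axis vector, never an assumed spacing.
* **Zones.** Closed intervals `[δ_min, δ_max]`; a point belongs iff
  `δ_min ≤ δ_k ≤ δ_max`. Zone operations touch nothing outside the zone
  (bit-equality, tested).
* **Phases.** Degrees at the interface; the first-order term spans the
  full spectral width relative to a pivot (window center by default).
* **Group delay.** Bruker digital-filter delay is removed by a circular
  left shift of the rounded delay before the transform, with the
  fractional residue corrected by a first-order phase across the spectrum.
  `GRPDLY` is used when present, else the published DECIM/DSPFVS table,
  else zero. This is standard practice; vendors do not document a single
  canonical scheme.

## Synthetic data generator

The generator emulates the artifacts the pipeline exists to remove:
per-sample chemical-shift jitter (Gaussian, SD in ppm, drawn once per
sample × peak), additive polynomial drift on a [−1, 1]-scaled coordinate,
white Gaussian noise, and factor-dependent multiplicative peak effects.
Lineshapes are Lorentzian only — the correct liquid-state 1D model and the
choice that keeps apex/half-height/area checks analytic. Multiplets are
first-order with binomial weights (1; 1:1; 1:2:1) and the pattern height
budget is split across components, so integrated pattern area tracks
`height` regardless of multiplicity. One RNG stream per plan, consumed in
a fixed order (jitter first, then noise, sample-major): identical plans
are bit-identical.

Time-domain counterpart: `Σ_k a_k exp(i2πν_k t − πw_k t)` sampled at the
dwell time, amplitudes scaled by `π w_k Δt` so the transform apex recovers
the plan height. The transform of this truncated, sampled decay is the
*digital* Lorentzian, which differs from the analytic lineshape by
O(w·Δt) ≈ 10⁻³ relative plus truncation wiggles; the frequency- and
time-domain routes therefore agree to ~1 % at the apex (tested), not to
float precision. Position and width agreement is at the single-axis-point
level, which is what the processing guarantees rely on.

What the generator does **not** emulate: solvent-suppression lineshape
distortion, ¹³C satellites, field inhomogeneity, t₁ noise, phase errors
that vary nonlinearly across the spectrum, and correlated (colored)
baseline noise. Passing tests therefore demonstrate algorithmic
correctness under the stated model, not robustness to every instrumental
artifact.

## Automatic phasing

Objective: `Σ min(0, Re S_k)²`, minimized over (φ₀, φ₁) by a 10° full
grid, a 1° grid inside the winning cell, then Nelder–Mead (xatol 10⁻⁴,
deterministic). The intermediate 1° pass exists because the penalty
surface holds shallow local minima between 10° nodes.

Identifiability is a property of the *spectrum*, not the optimizer: on a
noise-free spectrum the penalty is exactly zero for every phase pair that
keeps the real part nonnegative, and the width of that flat valley is set
by the absorptive/dispersive tail ratio at the points farthest from any
peak (≈ γ/Δ radians at distance Δ from a peak of half-width γ). Narrow
peaks flanked by long signal-free stretches pin both angles to well under
1°; spectra whose peaks sit near the axis edges leave φ₁ undetermined by
a degree or more, and no optimizer of this objective can do better. With
substantial noise the penalty's global minimum is genuinely biased in φ₁
for a fixed noise realization, so automatic phasing is meant for
high-SNR spectra; a warning is set when the phased result retains a large
negative fraction (e.g. pure noise).

## Baseline

Global: asymmetric least squares with second-difference penalty
(`smoothing`, default 10⁶ for ~8k-point spectra) and asymmetry `p`
(default 0.05), ≤ 10 reweighting passes. The estimator deliberately hugs
the lower envelope; on pure noise this leaves a positive offset of ~1–1.5
noise-SD at small `p` (an asymmetric-quantile property, not a bug). Where
noise is substantial relative to drift and an unbiased floor matters, a
more symmetric weight (`p ≈ 0.2`, offset ~0.5 SD) is the appropriate
setting; the acceptance scenario for drift removal uses it. Applying the
correction twice changes the result by well under 1 % of the first-pass
change when drift dominates noise.

Local: subtract the straight chord joining the zone-edge intensities
(edge value = mean of the 3 outermost in-zone points). Exact for linear
shoulders; the residual error is the neighbour tail's curvature over the
zone, which for a peak of half-width γ at distance Δ scales like
(zone width)³·γ/Δ⁴ — keep quantification zones narrow and a few half-widths
away from intense neighbours.

Solvent zones are zeroed and recorded on the set; every bucketing
strategy refuses or clips buckets that would intersect them.

## Alignment

* `calibrate`: whole-spectrum integer shift putting the zone apex on the
  reference ppm (TSP/DSS style); zero-fill at the vacated edge; an apex on
  the zone edge is ambiguous and raises.
* `align_zone_ls`: per spectrum, the integer shift in `[−m, m]` minimizing
  squared distance to the selection's mean segment; ties break toward the
  smaller magnitude; vacated points take the zone-edge value (zero-filling
  would create steps that corrupt neighbouring buckets). A best shift
  saturating at ±m is treated as out-of-range: unchanged + warning.
  Exact shift recovery holds when the jitter pattern is mean-centered;
  with a biased jitter distribution the mean reference itself is shifted
  and recovery is exact only up to that common offset.
* `align_zone_ptw`: polynomial warp in point coordinates fitted by
  Levenberg–Marquardt from the identity (cap 200·(degree+2) evaluations,
  tolerances 10⁻⁸), applied by linear interpolation. Warp coefficients are
  identifiable only if the zone pins ≥ degree+1 locations (two peaks for a
  linear warp); with one peak only the displacement at that peak is
  determined. A constant segment is singular: unchanged + warning.
* Both aligners compute the dispersion statistic (mean across-spectra SD
  over the zone) before and after and fall back to identity with a warning
  if it would increase — this is what converts the "same number of peaks
  in the zone" caveat of warping into safe behavior.
* Reference = mean over the selection (a median reference is not the
  minimizer of the least-squares objective, so mean is the default).

## Bucketing and SNR

AIB follows the recursive bin-value maximization with
`V(b) = Σ_s [(Imax − Iledge)(Imax − Iredge)]^R`, default `R = 0.5`; a
split must beat the parent's value and both children must exceed the noise
minimum, computed with the same formula on a hypothetical noise-only bin
(max = `noise_floor`, edges 0): `N·noise_floor^(2R)`. Leaves below the
minimum are dropped, so pure-noise zones yield no buckets. The
implementation is equality-tested against an independent brute-force
recursive maximizer on small zones.

SNR convention: `max(in-bucket intensity, 0) / (2σ)`, σ from the linear-
detrended user noise zone (≥ 32 points). The factor 2 is the halved
peak-to-peak convention; it is a convention, fixed so matrices are
comparable across runs. Bucket filtering keeps a bucket iff the fraction
of spectra with SNR ≥ threshold reaches `min_fraction`; it is monotone in
the threshold and only ever removes columns.

Integration: intensity sum × axis spacing (default; exactly additive
under bucket splits) or trapezoid on the in-bucket grid. Bucket labels are
`B<center ppm, 4 decimals>` with collision suffixes.

## Quantification and export

`conc(s,b) = C_ref·(A(s,b)/nH_b)/(A(s,ref)/nH_ref)` — scale-equivariant
per spectrum, exact when integrals capture whole patterns. Finite buckets
truncate Lorentzian tails (a ±30γ bucket captures ≈ 98 % of the area);
because reference and analyte zones use comparable geometry the ratio
error stays ~1 %, and the end-to-end synthetic recovery is within 3 %.
The workbook writes the five tables with full precision and stores the
formula in the file's description property; TSV exports use `%.17g`
(shortest-exact) floats so round trips are bit-faithful.

## Macros and batch replay

Every set-level operation appends a serializable command (operation,
parameters, optional `(factor, level)` selection) to the set's provenance;
re-applying that list to the raw input reproduces the processed matrix bit
for bit, because every operation is deterministic. The macro file is
line-oriented text (`op key=value … [@factor=level]`), ppm values with 4
decimals (kept exact whenever the rounding is lossless). Replay resolves
the vendor format per sample directory, processes FIDs with the macro's
`process` parameters, executes commands in order, logs each step with its
duration to the logging stream (never into payload files), and aborts with
the 0-based command index on failure. Two replays of the same macro on the
same input produce byte-identical export files.

## Problem sizes and defaults

Test and acceptance scenarios use 500 MHz spectra, 12 ppm windows and
2048–16384 points with 1–6 samples — sizes at which every stage is exact
or the discretization term is quantified, and the whole suite runs in
well under a minute. Default apodization is 0.3 Hz exponential (a mild ¹H
setting; the transform stage accepts any non-negative value), default
zero-fill is the next power of two, and the AIB resolution exponent
defaults to 0.5. These defaults are package choices, documented here
because no single community standard exists.

## Known limitations

* No lineshape deconvolution: overlapped patterns inside one bucket are
  integrated jointly.
* Automatic phasing assumes a dominantly absorptive, high-SNR spectrum
  (see above); pathological baselines should be corrected afterwards, not
  before.
* The nmrML reader/writer covers a pragmatic 1D subset (complex128 payload,
  optional zlib), not the full schema.
* Varian reading assumes a single data block per file as written by the
  fixture writer plus the standard big-endian block layout; multi-block
  arrayed experiments are concatenated naively.
* JEOL/Magritek formats, 2D data and instrument-specific solvent
  suppression are out of scope.
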