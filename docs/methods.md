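# Methods

This note documents the models, conventions and numerical choices behind
`punctakit`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show
about real microscopy data.

## Signal model of the synthetic generator

`punctakit.simulate` emulates a local-stimulation translocation
experiment: a dendrite imaged as a 1D fluorescence profile of length *L*
pixels, captured every 30 s for 13 frames (0–360 s). The noiseless trace is

    I(x, t) = B(t) · b · [1 + A(t) · Σ_p g_p(x)] ,

with baseline intensity *b* (default 100, arbitrary units), puncta shapes
*g_p* and three multiplicative/additive processes:

* **Kinetics.** Punctum amplitude (fold-over-baseline) follows a logistic
  rise
  `A(t) = a0 + (a_max − a0) / (1 + exp(−(t − t_half)/τ))`
  with midpoint `t_half = 150 s` and slope scale `τ = 30 s`, so the
  plateau is reached within 5–6 min (A(360 s) is within 0.1% of `a_max`).
  The initial amplitude `a0` (default 0.6) models puncta already present
  at the first post-stimulation capture. This is deliberate, not
  cosmetic: dendrites in this preparation show pre-existing bright puncta
  that subsequently brighten, and the downstream read-out normalizes each
  dendrite to its *initial* punctal fluorescence — which requires
  detectable initial puncta. A pure zero-baseline sigmoid (`a0 = 0`)
  would make frame 0 punctum-free and every dendrite unnormalizable under
  per-frame detection; it remains available as the `amplitude_init = 0`
  special case. Defaults `a0 = 0.6`, `a_max = 2.0` put the vehicle
  plateau of the relative read-out near 1.6–1.7, i.e. a 60–70% rise —
  the order of magnitude seen in strong translocation; inhibited
  conditions are modeled by lowering `a_max` (0.7 in the default config,
  plateau ≈ 1.05).
* **Punctum shape.** Gaussian with FWHM = `puncta_width` (default 5 px),
  truncated to zero beyond ±2·FWHM. Detection-module unit tests use 5-px
  boxcars instead wherever exact window arithmetic is wanted, so both
  shapes are exercised.
* **Bleaching.** A single multiplicative factor per frame,
  `B(t) = exp(−t / bleach_tau)`, applied to signal and background alike —
  exactly the regime a first-frame-ratio correction undoes.
* **Noise.** Additive Gaussian per pixel (SD `noise_sd`, default 5 = 5%
  of baseline in the pipeline config), clipped at zero. Intensity
  *independent* by design; Poisson/shot-noise mixing, PSF convolution,
  drift and focus changes are not modeled.

Randomness: one `SeedSequence` per dataset; dendrite *i* consumes spawned
child stream *i*, so the first *n* dendrites are bit-identical no matter
how many more are generated. Punctum positions are either fixed
(`puncta_positions`) or drawn per dendrite with a 31-px minimum separation
so neighbouring detection windows stay disjoint.

What passing synthetic benchmarks therefore shows: the pipeline's
*arithmetic* (windows, quotients, normalizations, SS decomposition) is
correct and its recovery properties hold under a flat-background,
isolated-puncta, Gaussian-noise world. It does not certify performance on
real dendrites with varying background, crossing processes, spine
geometry or shot noise.

The 2D renderer paints the 1D profile into an image: every pixel within
`render_width/2` of the polyline takes the value of its nearest arc-length
sample, so the band is uniform across its width and wide-linescan
extraction is its exact inverse on straight paths.

## Linescan extraction

Coordinates are 0-based `(row, col)` with pixel centers at integers.
Profiles sample the polyline at unit arc-length steps
(`L = floor(total length) + 1` samples); at each step the intensity is the
mean of `width` bilinear samples at unit spacing along the local
perpendicular, centered on the path — for the default even width 18 the
offsets are −8.5 … +8.5, straddling the centerline symmetrically. Local
direction comes from the segment the sample falls on; no corner smoothing
(corner artifacts are sub-pixel at 18-px widths). Samples that leave the
frame raise a geometry error naming the first offending arc position —
silent clamping would corrupt puncta near path ends.

## Bleach correction

`ratio[t] = total(frame 0) / total(frame t)`; `ratio[0]` is set to 1.0
exactly. "Total fluorescence" is computed over the extracted trace by
default; whole-frame totals can be supplied when stacks are available
(`bleach_scope: frame`) — which of the two the original acquisition
software used is not recoverable, so both are exposed. An optional 3-px
median pre-filter (`smooth: true`, off by default) stands in for
unspecified acquisition-software morphology filtering. The correction is
idempotent and conserves totals to < 1e−12 relative on multiplicative
bleach; because the downstream quotient detector and the
relative-to-total read-out both cancel per-frame scalars, the correction
provably cannot change detections or `rel_fluor` — it exists to make
intermediate intensity tables comparable across frames.

## Puncta detection

Valid-mode moving averages of 5 and 31 px, both indexed by window-center
pixel; quotients exist only where the 31-px window fits, so the 15-px
margins at each profile end carry no detections (truncated edge windows
would inflate quotients). The threshold comparison is strict
(`quotient > 1.1`). A punctum is one maximal run of flagged pixels — no
minimum run length and no gap merging by default (`min_run_length`
exposes a filter, off by default); its center is the position of the
maximal quotient in the run, and regions are reported 0-based half-open.
Detection is per frame, independently; no punctum identity tracking
across frames (a reference-frame detection mode would be the natural
extension but is not implemented). Consequences worth knowing: detection
is invariant to positive rescaling but *not* to additive offsets (a large
ambient pedestal pushes quotients toward 1), and a 5-px punctum needs
roughly ≥ 1.3× baseline contrast (Gaussian shape) or ≥ 1.2× (boxcar) for
its center quotient to clear 1.1.

## Translocation read-out

Per frame: punctum intensity = sum of the corrected profile over the
region; relative value = intensity / frame total; dendrite value = mean
over whatever puncta exist at that frame (region sum, not run maximum —
sums are robust to single-pixel noise). The per-dendrite series is then
divided by its frame-0 value; dendrites with no frame-0 puncta cannot be
normalized and are excluded with a logged warning; frames after frame 0
with no puncta yield NaN and the pipeline drops such dendrites before the
balanced ANOVA. Decreases at initially bright puncta are included in the
average, not special-cased. Dendrites — not neurons — are the unit of
observation throughout. The canonical report times are 90, 240 and 360 s
(early / mid / late).

## Statistics

Split-plot decomposition with weighted marginal means; because every
subject carries every time level, cell frequencies are proportional even
with unequal group sizes and the decomposition is exact (total SS
conserved to 1e−9 relative, asserted). F ratios: condition against
subjects-within-condition; time and condition×time against
time×subjects-within-condition. Degenerate designs raise errors rather
than imputing; the all-constant corner case (zero within-subject
variation) reports F = 0, p = 1.

Box's epsilon is estimated from the covariance of within-subject
residuals pooled across conditions (divisor N − G) — the raw covariance
across all subjects would absorb between-group trajectory separation and
spuriously deflate ε. ε is clamped to [1/(k−1), 1]; a centered covariance
of exactly zero (no within-subject residual variation) trivially
satisfies sphericity and yields ε = 1. GG-corrected p values multiply
both dfs of the within-subject tests by ε; the between-subjects test is
unaffected by sphericity and is not corrected. p values come from the F
survival function via scipy's regularized incomplete beta.

Simple main effects are one-way between-condition ANOVAs computed on each
time point's own error term (robust to variance growth over time, which
this data shows), Šidák-adjusted over the number of tested time points;
pairwise pooled-variance t contrasts are adjusted over the pairs within
each time point. Levene's test uses absolute deviations from group means
(the classic statistic), exposed both pooled over time and per time
point.

**Known limitation — GG conservatism under true sphericity.** With k = 13
time levels and ~18–45 residual df, the sample ε is biased well below 1
even when the true covariance is compound-symmetric (mean ε̂ ≈ 0.59 for
true ε = 1 at 18 df), so the GG-corrected interaction test is
conservative in exactly the situation that needs no correction: its
empirical type-I error under a compound-symmetric null (2 × 10 subjects)
is ≈ 0.02 at nominal 0.05, where the uncorrected test is exact. Under
genuine sphericity violation the correction does its job: in a
heteroscedastic-time simulation the uncorrected test inflates to ≈ 0.10
while the GG test stays near 0.04. This is the classic trade-off of the
Greenhouse–Geisser procedure; the Huynh–Feldt refinement that reduces the
bias is out of scope. Power is unaffected in practice: a vehicle-like
(plateau 1.5) vs fully-inhibited (plateau 1.05) contrast at n = 10/group
is detected in essentially 100% of simulations.

Monte Carlo calibrations use the compound-symmetric trajectory model
(`simulate_rm_matrices`: subject random intercept SD 0.15, residual SD
0.15 → intraclass correlation 0.5, values on the rel_fluor scale) rather
than the full imaging pipeline — the statistical properties under test do
not depend on the imaging layers, and this keeps 1000-replicate runs in
seconds. Problem sizes throughout (200 benchmark dendrites, 10/condition
pipeline runs, 1000 null + 200 effect replicates) were chosen to make
Monte Carlo standard errors small relative to the asserted bounds.

## Pipeline and reproducibility

`run_pipeline` is a pure function of (config, inputs): per-condition
simulation seeds derive deterministically from the master seed, every
output CSV carries a hash of the analysis-relevant config (output
directory excluded) in a header comment, and identical config + seed
reproduce all artifacts byte-for-byte. Errors abort with the stage name
and offending dendrite id. The three input modes (simulate / linescan CSV
/ TIFF stacks + path annotations) converge on the same trace
representation, so simulate-then-reload through CSV is exactly equivalent
to in-memory simulation.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| frame_interval | 30 s | capture period |
| n_frames | 13 | 0–360 s series |
| linescan width | 18 px | perpendicular averaging width |
| pixel_size | 0.2 μm/px | lateral calibration (a stand-in; set per rig) |
| short/long window | 5 / 31 px | detection moving averages |
| quotient threshold | 1.1 | strict `>` comparison |
| amplitude_init / max | 0.6 / 2.0 | punctum fold-over-baseline, t = 0 / plateau |
| t_half, τ | 150 s, 30 s | logistic kinetics |
| noise_sd | 5 (pipeline) | Gaussian pixel noise, 5% of baseline |
| report times | 90 / 240 / 360 s | early / mid / late |
| alpha | 0.05 | significance level |

The 0.2 μm/px calibration is a placeholder for a typical 40–60×
configuration, not a measured value; puncta densities scale inversely
with it, so set it from the actual rig before interpreting densities.
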