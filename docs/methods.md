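# Methods

## Problem and data model

The pipeline quantifies gait variability from markerless pose estimation.
Each walking trial is an ordered stream of frames, each frame 17 keypoints
`[x, y, confidence]` in pixel units (image convention, origin top-left).
Feet are identified purely by index — 15 left, 16 right — never by
geometry, so a mislabeled pose upstream stays mislabeled rather than being
silently "fixed". Subjects perform the SPPB walking component twice
(trials 2.1 and 2.2); each trial contributes one left-foot and one
right-foot displacement-variance feature.

Frame rate and pixel calibration are deliberately left out: all
displacement quantities are pixels per frame and variances pixels², and
every downstream statistic (correlations, PCA on standardized features) is
invariant to a global rescaling, so absolute calibration would add nothing.

## Feature extraction

1. **Confidence filtering.** A frame is dropped from *both* foot tracks
   when either foot's confidence falls below `min_confidence` (default
   0.3), keeping the tracks time-aligned. Dropped frames are removed, not
   interpolated; the two displacements flanking a gap merge into one
   displacement across it. This is conservative — interpolation would
   manufacture motion — and an option (`skip_gap_spanning`) excludes
   gap-spanning displacements entirely for sensitivity analysis. Fewer
   than two surviving frames is an explicit error, never a silent NaN.
2. **Displacements.** Euclidean distances between consecutive surviving
   coordinates.
3. **Variance.** Unbiased sample variance (denominator n−1) about the
   *same trial's* mean displacement. The mean is per-trial because the
   variance is meant to measure within-trial fluctuation; pooling means
   across trials would mix inter-trial level differences into it.
4. **Composite.** `var_mean` averages the four per-foot/per-trial
   variances; per-trial means average the two feet. Any missing term is a
   hard error listing exactly what is absent.

## PCA gait index

PCA is computed on the **sample correlation matrix** of the four variance
features (z-scored columns, `numpy.linalg.eigh`), not the covariance:
the index's interpretation rests on symmetric ±0.5 loading patterns, which
are attainable exactly only after standardization, and the features share
units but not scale across subjects of different stride length. The
explained-variance ratio of a component is its eigenvalue over the trace
(= 4); for feature data lying in a two-dimensional latent subspace the two
ratios sum to exactly 1.

Signs are fixed deterministically: PC1 so its loading sum is positive,
PC2 so the trial-1 loadings are positive (falling back to loading sum,
then first nonzero entry, so orientation is total). Eigenvalue order uses
a stable sort. Interpretation is earned, not forced: PC1 is labelled
"muscle-control reserve" only when all four loadings share one sign, PC2
"learning-fatigue response" only when trial-1 and trial-2 loadings oppose;
anything else is reported as "unstructured". Under a block-exchangeable
correlation structure (within-trial correlation a, all cross-trial
correlations b) the swap symmetries force the eigenvectors to
(1,1,1,1)/2 with eigenvalue 1+a+2b and (1,1,−1,−1)/2 with 1+a−2b; for
a=0.6, b=0.2 the explained ratios are exactly 0.5 and 0.3 — this analytic
case anchors the acceptance checks.

Note one consequence of the correlation convention: rescaling any single
feature column changes neither loadings nor scores (z-scores absorb the
scale). This is the invariance the tests assert.

## Mixed-type correlation engine

Variables are classified binary / ordinal / continuous — in the cohort
schema: gender binary; the per-trial and combined test scores ordinal;
demographics, durations and all gait features continuous. Auto-detection
(2 levels → binary; integer-valued with ≤ 6 levels → ordinal) exists for
ad-hoc tables, but the pipeline always passes explicit kinds, which win.
Constant columns are excluded with a warning.

Per-pair dispatch: binary×binary undefined (rendered blank — returning a
number would fabricate an association); binary×numeric point-biserial
(Pearson on 0/1 coding); ordinal×ordinal Kendall τ-b (tie-corrected, since
SPPB scores tie heavily); ordinal×continuous Spearman; continuous×
continuous Pearson. Ordinals are midranked and z-scored first; binary
variables are 0/1 coded with levels in sorted order.

LOWESS smoothing of continuous variables (statsmodels, against subject
presentation order, fraction 0.5) is implemented but **off by default**:
pre-smoothing alters the sampling distribution of classical coefficients,
and since the exact covariate/fraction such smoothing would use is not
recoverable for the original analysis, it is exposed as an explicit option
rather than silently applied.

p-values are two-sided asymptotic; a permutation option exists for very
small samples. The Benjamini–Hochberg family is all off-diagonal pairs of
the rendered matrix, matching a single multiple-comparison correction over
one heatmap. Stars are assigned from the **adjusted** p-values
(* < 0.05, ** < 0.01, *** < 0.001); coefficients print to two decimals
with half-up rounding (−0.955 → "−0.96").

## Synthetic data generator

`simulate_walk_trial` advances each foot along the image x-axis at fixed
height by per-frame increments

    step_k = max(0, (step_mean + trend·k)·s·g_k + N(0, step_sd·s)),

where s is 1 for the left foot and `lr_asymmetry` for the right, and
`g_k = 1 + cycle_amplitude·sin(2π(k/cycle_period + phase))` is an optional
alternating-gait modulation (the right foot's phase is offset by half a
cycle by default). The modulation amplitude defaults to 0 so that the
zero-noise, zero-trend trial produces *exactly* constant steps and hence
exactly zero displacement variance through the full pipeline — a sharp
correctness anchor that an always-on oscillation would destroy. Because
feet move at constant image height, a foot's frame-to-frame Euclidean
displacement equals its step increment, so the generative step variance is
the quantity the pipeline must recover (verified against a Monte-Carlo
re-simulation of the step rule). Confidence dropout marks a frame's foot
keypoint with confidence below 0.3 at the configured rate; torso keypoints
are laid out plausibly above the mid-foot point.

`simulate_cohort` draws per-subject step statistics (defaults: step mean
6–12 px, step SD 1–4 px, trend ±0.004 px/frame, left-right asymmetry
0.9–1.1, 300 frames/trial, 2% dropout — spreads wide enough that var_mean
varies several-fold across subjects, as the per-subject heterogeneity in
stride patterns requires), simulates both trials, computes var_mean
through the actual extraction pipeline, and generates durations from the
linear link

    duration_j = intercept_j + (β/2)·var_mean + ε_j,  ε_j ~ N(0, noise_sd/√2),

so the *total* duration follows `intercept + β·var_mean + N(0, noise_sd)`
exactly and the closed form ρ = βσ_vm / √(β²σ_vm² + noise_sd²) applies to
it. Trial 1 gets a positive intercept offset (default 1.5 s), emulating
the adaptation effect that makes first walks slower. Ordinal scores follow
from per-trial durations through configurable thresholds (defaults 2.0 /
3.0 / 4.5 s chosen so default cohorts span scores 1–4); the combined score
is the better trial. Defaults are sized so durations stay positive without
clipping (clipping would break the exact noiseless linearity the tests
rely on). Cohort defaults mirror the study frame: 19 subjects, 15/19 male,
ages 60+.

What the generator does **not** emulate: real pose-estimation error
structure (correlated jitter, identity switches, occlusion bursts),
biomechanical gait dynamics (stance/swing phases, turning), camera
perspective effects, and any nonlinearity or confounding in the
duration–variability relationship. Passing tests therefore demonstrate
that the *statistical machinery* is correct and recovers planted structure
— not that the clinical association holds in real cohorts, which only the
original (undeposited) recordings could show. Reported small-sample
correlations from such cohorts are treated as directional expectations
only.

Two structured generators support the analytic PCA scenarios:
`features_with_exact_correlation` empirically whitens Gaussian draws and
recolors them by a Cholesky factor so the *sample* correlation equals a
target matrix to machine precision, and `rank2_features` builds the four
variances from exactly two latent factors.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  configs and seeds give byte-identical keypoint JSON (shortest round-trip
  float representation) and bit-identical pipeline manifests (SHA-256 per
  artifact, no timestamps anywhere in outputs).
- Variance uses a numerically plain centered two-pass sum; equality with
  an independent textbook implementation to 1e−12 relative is asserted
  over 1000 random series.
- Eigenvectors come from `eigh` (symmetric solver); the test-suite oracle
  is an independent power-iteration-with-deflation solver.
- Printed percentages and coefficients use decimal half-up rounding, the
  convention of the summary tables they feed.
- Degenerate inputs fail loudly: too few frames/subjects/pairs, zero
  variance where spread is required, missing trials (named per subject),
  malformed JSON (with line context), out-of-range confidences.

## Problem sizes

Default study-scale runs use 19 subjects × 2 trials × 300 frames. The
recovery check uses cohorts of 200 subjects × 150 frames over 20 seeds,
with σ_vm estimated from a 400-subject noiseless pilot; the determinism
check runs a 50-subject, 500-frame cohort twice. These sizes make the
statistical assertions sharp (mean recovered ρ within ±0.05) while keeping
the whole suite fast on a single CPU.

## Known limitations

- The confidence-filtering policy (drop-and-merge) is this package's
  choice; other handling of missing detections would perturb variances.
- LOWESS-then-correlate, when enabled, changes coefficient null
  distributions; its p-values should be read qualitatively.
- Binary×binary association is intentionally not computed; use a
  contingency measure outside this engine if needed.
- The ordinal score scale is SPPB-style 0–4 by assumption and
  configurable; scores enter correlations through ranks only.
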