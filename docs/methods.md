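# Methods

This note documents the models the package implements, the numerical choices made
where the procedure left latitude, what the synthetic generator does and does not
emulate, and known limitations.

## Mono-exponential relaxometry

The signal model is `S(t) = S0·exp(−t/T)` per voxel, fitted by unweighted
Levenberg–Marquardt least squares on magnitude data. Magnitude MRI noise is Rician,
not Gaussian; fitting without a noise-floor term biases T slightly downward at low
SNR, and the package deliberately makes no Rician correction — the maps it produces
are therefore directly comparable to standard mono-exponential pipelines. With only
four preparation times, bi-exponential decompositions are not identifiable and are
out of scope.

Numerical choices:

* **Initialization** — closed-form two-point start: `S0₀` = first signal,
  `T₀ = (t_last − t_first)/max(ln(S_first/S_last), 1e−6)`, clipped to
  `[1e−3, 10·t_max]`. On decaying data this lands near the optimum and makes the
  noiseless fit converge to machine precision.
* **Divergence cap** — fits with `T > 10·t_max` (450 ms on the default spin-lock
  grid) are marked failed: at the sampled times such a decay is indistinguishable
  from a constant. Constant signals therefore yield `fit_ok=False`, not a number.
* **Failure handling** — non-convergence, non-positive T or S0, and all-zero
  signals are recorded in the validity mask, never propagated as values. Downstream
  region means use valid voxels only; failed voxels are excluded, not imputed.
* **Default preparation grids** — TSL 0/15/30/45 ms (T1ρ) and TE 0/10.4/20.8/41.6 ms
  (T2), the acquisition protocol the package targets.
* **Upper thresholds** — 100 ms (T1ρ) and 80 ms (T2), strict comparison: a voxel
  exactly at the threshold survives. The cut removes synovial-fluid and
  partial-volume voxels, whose relaxation times are far above cartilage.

The test suite checks the fitter against an independent exhaustive grid search over
`T ∈ (1, 200]` ms in 0.01 ms steps with the amplitude profiled out by linear least
squares; agreement is required within 0.1 ms on noisy data.

## Subregion geometry

Wedge `k ∈ 1..8` covers the half-open interval `[(k−1)·45°, k·45°)` measured
counterclockwise from the reference line, in the displayed image plane (x = columns
rightward, y = up the image). The convention is arbitrary but fixed; the synthetic
truth uses the same convention, so labels and truth agree by construction. The
wedge assignment is computed per slice about one shared head center — the femoral
head is treated as a single sphere, and angles are in-plane rather than spherical.
A voxel exactly at the head center has no defined angle and is excluded (counted
and logged). Region means are arithmetic means over valid voxels; the whole-
cartilage mean averages voxels directly rather than averaging subregion means, so
unequal wedge sizes cannot distort it.

## Voxel-based statistics

Paired two-sided Student's t-test per voxel, restricted to voxels where every
subject pair is valid (the pair-count threshold is configurable). No multiple-
comparison correction is applied by default — the summary statistic is the
percentage of tested voxels with p < α, which is interpretable against the binomial
chance level rather than against a corrected threshold. A Benjamini–Hochberg
adjustment is available off the main path. Degenerate voxels: all-zero differences
give p = 1 (no evidence); zero-variance nonzero differences give a p = 0 sentinel
with an aggregated warning, keeping the fraction statistic well defined. Left and
right hips of one participant enter as separate paired units, which ignores
within-participant correlation of the two hips; the voxel-wise inference is
therefore slightly anticonservative in the same way conventional bilateral VBR
analyses are.

## Z-score calibration

Per-voxel statistics (sample SD, n−1) are the default scope; a global scalar scope
is available. Clamping at ±4 standard scores is applied to the z-score *before*
rescaling, so a calibrated value can never leave the reference distribution by more
than 4 SD. Voxels with fewer than two contributors or zero spread are flagged
unusable and masked in z-maps and calibrated maps; the contrast's upper threshold
is re-applied after calibration.

Direction: the transform standardizes against the *target* scanner's statistics
and re-expresses in the *reference* scanner's — the direction a longitudinal study
needs when a late timepoint arrives on a new scanner and must be made comparable to
earlier data. The reverse mapping is obtained by swapping the statistics arguments.

A practical caveat the transfer experiments make explicit: per-voxel statistics
estimated from a small calibration cohort (n ≈ 16 hips) carry estimation noise of
the same order as the paired-test standard error, which re-inflates the
significant-voxel fraction when those statistics are transferred to an independent
cohort. When the scanner bias is globally affine, global-scope statistics are
exactly sufficient and carry negligible estimation noise, so the transfer
experiments in the acceptance checks use global scope; per-voxel scope remains the
default for self-calibration, where the paired mean difference cancels exactly.

## Longitudinal model

Fixed effects acquisition-year + sex + age + KL-score + BMI with no global
intercept, random intercept per participant, REML (ML available for the null-vs-
full likelihood-ratio comparison, which uses nested intercept-bearing
parameterizations so the statistic is nonnegative by construction). Sex is coded
female = 1. Hips are not a random level — both hips of a participant share one
random intercept — matching the single-grouping-factor design and accepting the
same simplification.

Inference uses a t reference with a within/between degrees-of-freedom split in the
style of classical nested-model software: terms that vary within participants
(acquisition year, BMI) get `n_obs − n_groups − n_within` degrees of freedom;
participant constants (sex, age, KL-score) get `n_groups − n_between`. On the
default cohort geometry (18 participants × 2 hips × 5 years) this gives 160 and 15.
Simulation checks show the resulting inference is calibrated there: 95% CIs cover
the generating BMI coefficient in ≈92–95 of 100 replicates, and p-values of a null
year effect pass a Kolmogorov–Smirnov uniformity check. Rank-deficient designs are
rejected up front naming the most collinear pair; singular fits (random-intercept
variance at the boundary) are returned with a flag, and a cohort with fewer than
two participants is an error since no between-participant variance is identifiable.
Kellgren–Lawrence grades above 3 (advanced OA) are excluded when the long table is
built, mirroring the usual inclusion criterion for early-to-moderate OA cohorts.

## Synthetic generator

What it emulates: annular two-band cartilage geometry around a femoral-head center
(inner band femur, outer band acetabulum, ≥1 voxel gap); per-hip truth maps
composed of a base value (defaults T1ρ 35 ms, T2 28 ms — plausible hip-cartilage
magnitudes, not measured claims), a participant offset (SD 2 ms), a smooth
two-plane-wave spatial texture, optional focal lesions (disc of elevated T inside
one wedge), and covariate effects (BMI, sex, year, KL) entering as linear slopes;
affine scanner observation models `a·T + b + N(0, σ²)` per voxel — the weakest
bias model under which Z-score calibration is exactly correct; forward-simulated
echo series; and the two study designs (same cohort on two scanners; 5-year cohort
with a scanner switch in the final year). Covariates mirror an early-to-moderate
hip-OA cohort: age ~ N(53, 15), two-thirds female, BMI ~ N(26, 4) with a small
yearly random walk (SD 0.3 kg/m²), KL grades weighted 17:15:3:1 across 0–3.

What it does not emulate: registration error (data are generated pre-aligned),
anatomically realistic cartilage shape, Rician noise floors, coil/B1 effects, or
spatially varying scanner bias (available as an extension point but not default).
Passing tests therefore demonstrate correctness of the statistical machinery under
the stated models, not robustness to registration failure or non-affine scanner
differences.

Determinism: every random quantity comes from a stream keyed by
(master seed, purpose tag, entity indices), so any subset of a cohort regenerates
identically, and a pipeline run reproduces byte-identical artifacts from one
configuration.

## Problem sizes

The default synthetic atlas is 4 slices × 128 × 128 with ≈3700 cartilage voxels;
pipeline smoke configurations use 64 × 64 grids. Calibration experiments use 8
participants × 2 hips (the calibration-study geometry); mixed-effects recovery
uses 18 participants × 2 hips × 5 years with 100 replicates. These sizes make the
statistical checks sharp (binomial envelopes of a few tenths of a percent) while a
full test-plus-acceptance run completes in a few minutes on one CPU.

## Known limitations

* Per-voxel fitting loops in Python over `scipy.optimize.least_squares`; at atlas
  resolution this is seconds per map, not suitable for whole-volume clinical
  matrices without batching.
* The degrees-of-freedom split is a convention, not an exact distribution;
  Satterthwaite-type approximations are not provided.
* The pipeline driver covers the synthetic two-scanner study end to end; applying
  it to real data means supplying registered NIfTI series and masks in the
  documented layout.
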