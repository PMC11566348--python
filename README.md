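# hiprelax

Quantitative hip-cartilage relaxometry analysis in Python: mono-exponential
T1ρ/T2 map fitting, atlas-space angular subregion analysis, voxel-based
relaxometry (VBR) group statistics, inter-scanner Z-score calibration, and
longitudinal mixed-effects trajectory modelling — plus a synthetic cohort
generator with known ground truth that exercises every stage.

## Who this is for

Researchers analyzing compositional MRI of articular cartilage — T1ρ (spin-lock)
and T2 (multi-echo) relaxation times are sensitive to proteoglycan content and
collagen/hydration, and their increase over time is an imaging biomarker of
osteoarthritis progression. The package covers the analysis chain downstream of
image registration: all inputs are assumed aligned to a common atlas space.

## The methods at its core

**Map fitting.** Each voxel's magnitude signal across preparation times *t*
(spin-lock times TSL for T1ρ, echo times TE for T2) follows

    S(t) = S0 · exp(−t / T)

and (S0, T) are estimated by unweighted Levenberg–Marquardt least squares.
Fitted maps are cleaned with strict upper thresholds (T1ρ > 100 ms, T2 > 80 ms
→ invalid) that remove fluid and partial-volume voxels.

**Subregions.** Each sagittal slice is divided into eight 45° wedges R1–R8
about the femoral-head center, measured counterclockwise from a reference line
parallel to the femoral neck; wedges R2–R6 (femur) and R2–R5 (acetabulum) are
analyzed, and any wedge with fewer than 50 voxels across the analyzed slices is
dropped.

**VBR.** With all subjects in one atlas space, groups are compared with a
two-sided paired Student's t-test at every voxel (p < 0.05, uncorrected), and
summarized as the percentage of tested voxels that are significant.

**Z-score calibration.** Given group statistics (mean, SD) of one cohort imaged
on both scanners, a target-scanner value is standardized, clamped to ±4, and
re-expressed in the reference scanner's distribution:

    z = clip((T_target − mean_target) / sd_target, −4, +4)
    T_calib = z · sd_reference + mean_reference

When the scanner difference is affine this removes it exactly.

**Trajectories.** Region means over yearly visits are modelled with a linear
mixed-effects model — fixed effects acquisition-year + sex + age + KL-score +
BMI with no global intercept, a random intercept per participant, REML — and
with percentage change, `100·(followup − initial)/initial`.

## Worked example

`examples/two_scanner_calibration.py` simulates an 8-participant cohort (16
hips as paired units) observed through two scanners, the second with an affine
bias (scale 1.1, offset +2 ms, voxel noise 1.5 ms), and prints:

```
significant voxels before calibration: 100.00 %
significant voxels after calibration :   0.00 %
```

Before calibration the paired t-test flags essentially every cartilage voxel as
differing between scanners; after Z-score calibration with the cohort's
per-voxel statistics, no voxel differs — the bias is gone. The other examples
cover map fitting (`fit_relaxation_map.py`), subregion means
(`subregion_analysis.py`), the mixed-effects model (`longitudinal_lme.py`,
which recovers generating coefficients bmi ≈ 1.2 and year ≈ 0.9 within their
standard errors), and the staged pipeline driver (`full_pipeline.py`).

A thin CLI mirrors the library (`hiprelax simulate | fit | regions | calibrate
| vbr | longitudinal | run`); `hiprelax run --config study.yaml` executes the
full staged pipeline with provenance tracking and byte-identical re-runs.

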