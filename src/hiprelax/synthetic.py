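"""Synthetic hip-cartilage cohorts with known ground truth.

The generator emulates the data the analysis pipeline consumes, already in atlas
space: an annular two-band cartilage geometry (inner band = femoral cartilage, outer
band = acetabular cartilage) around a femoral-head center, per-subject relaxation-time
truth maps with smooth spatial texture, focal lesions and covariate-driven effects,
affine scanner observation models (scale, offset, voxel noise), forward-simulated
echo series, and full two-scanner and longitudinal study designs.

Every quantity is reproducible from the master seed: each (entity, purpose) pair gets
its own deterministic random stream, so regenerating any subset gives identical
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import AtlasGeometry, filter_small_subregions, partition_subregions, region_mean
from .errors import InputError
from .relaxometry import (
    Contrast,
    DEFAULT_TIMES_MS,
    EchoSeries,
    RelaxationMap,
    apply_upper_threshold,
)
from .vbr import VoxelStack

__all__ = [
    "ScannerModel",
    "LesionSpec",
    "CohortConfig",
    "make_atlas",
    "draw_covariates",
    "simulate_truth_maps",
    "apply_scanner_model",
    "simulate_echo_series",
    "simulate_two_scanner_study",
    "simulate_lme_table",
    "simulate_longitudinal_cohort",
]

# Stream tags keep per-purpose random streams independent.
_T_COVARIATES = 1
_T_SUBJECT = 2
_T_FIELD = 3
_T_LESION = 4
_T_SCANNER = 5
_T_ECHO = 6
_T_LME = 7

_CONTRAST_KEY = {Contrast.T1RHO: 0, Contrast.T2: 1}


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), *map(int, key)])


@dataclass(frozen=True)
class ScannerModel:
    """Affine observation model of one scanner: observed = scale*T + offset + noise."""

    scale: float = 1.0
    offset_ms: float = 0.0
    noise_sd_ms: float = 0.0
    id: str = "scanner"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise InputError("scanner scale must be positive")
        if self.noise_sd_ms < 0:
            raise InputError("noise_sd_ms must be nonnegative")


@dataclass(frozen=True)
class LesionSpec:
    """Focal lesion: an in-plane disc of elevated relaxation time inside one wedge."""

    region: int = 3
    radius_vox: float = 3.0
    elevation_ms: float = 8.0
    prevalence: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise InputError("lesion prevalence must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a simulated cohort.

    Defaults emulate the calibration-study geometry: 8 participants, both hips, one
    timepoint, plausible cartilage values (T1rho ~35 ms, T2 ~28 ms).  Covariate
    effect sizes are per-unit slopes added to the truth value; they default to zero
    so each study switches on only the effects it needs.
    """

    n_participants: int = 8
    hips_per_participant: int = 2
    timepoints: int = 1
    base_mean_ms: dict = field(
        default_factory=lambda: {Contrast.T1RHO: 35.0, Contrast.T2: 28.0}
    )
    between_subject_sd_ms: float = 2.0
    spatial_sd_ms: float = 1.0
    bmi_slope_ms: float = 0.0  # ms per kg/m^2 above bmi_ref
    year_slope_ms: float = 0.0  # ms per study year
    sex_offset_ms: float = 0.0  # added for female participants
    kl_slope_ms: float = 0.0  # ms per KL grade
    bmi_ref: float = 25.0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_sd_ms < 0 or self.spatial_sd_ms < 0:
            raise InputError("standard deviations must be nonnegative")


def make_atlas(
    grid_shape: tuple[int, int, int] = (4, 128, 128),
    head_center: tuple[float, float] = (64.0, 64.0),
    femur_radii: tuple[float, float] = (20.0, 23.0),
    acetab_radii: tuple[float, float] = (25.0, 28.0),
    reference_angle_deg: float = 0.0,
) -> AtlasGeometry:
    """Deterministic annular atlas: femoral band inside, acetabular band outside.

    The two radius bands (inclusive) must be disjoint with at least a one-voxel gap.
    """
    f0, f1 = femur_radii
    a0, a1 = acetab_radii
    if f1 < f0 or a1 < a0:
        raise InputError("radius bands must have nonnegative width")
    if a0 <= f1 + 1.0:
        raise InputError("femoral and acetabular bands must be separated by >= 1 voxel")
    _, n_rows, n_cols = grid_shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    r = np.hypot(rows - head_center[0], cols - head_center[1])
    femur2d = (r >= f0) & (r <= f1)
    acetab2d = (r >= a0) & (r <= a1)
    femur = np.broadcast_to(femur2d, grid_shape).copy()
    acetab = np.broadcast_to(acetab2d, grid_shape).copy()
    if not femur.any() or not acetab.any():
        raise InputError("a radius band produced an empty mask")
    return AtlasGeometry(
        grid_shape=grid_shape,
        head_center=head_center,
        reference_angle_deg=reference_angle_deg,
        femur_mask=femur,
        acetab_mask=acetab,
    )


def draw_covariates(config: CohortConfig) -> pd.DataFrame:
    """Per-participant-per-year covariates (age, sex, BMI, KL-score).

    Age, sex and KL-score are baseline constants; BMI takes a small yearly random
    walk so it varies within participants.  Distributions mirror an early-to-moderate
    hip-OA cohort: age ~ N(53, 15) years, ~2/3 female, BMI ~ N(26, 4) kg/m^2, KL
    grades 0-3 weighted toward the mild end.
    """
    rng = _rng(config.seed, _T_COVARIATES)
    rows = []
    for p in range(config.n_participants):
        age = float(np.clip(rng.normal(53.0, 15.0), 20.0, 85.0))
        sex = "F" if rng.random() < 2.0 / 3.0 else "M"
        kl = int(rng.choice([0, 1, 2, 3], p=[17 / 36, 15 / 36, 3 / 36, 1 / 36]))
        bmi = float(np.clip(rng.normal(26.0, 4.0), 18.0, 40.0))
        for year in range(config.timepoints):
            if year > 0:
                bmi = float(np.clip(bmi + rng.normal(0.0, 0.3), 18.0, 40.0))
            rows.append(
                dict(
                    participant_id=f"P{p:02d}",
                    acq_year=year,
                    age=age,
                    sex=sex,
                    bmi=round(bmi, 2),
                    kl_score=kl,
                )
            )
    return pd.DataFrame(rows)


def _smooth_field(atlas: AtlasGeometry, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean smooth spatial texture: two random low-frequency plane waves."""
    if amplitude == 0:
        return np.zeros(atlas.grid_shape)
    _, n_rows, n_cols = atlas.grid_shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    field2d = np.zeros((n_rows, n_cols))
    for _ in range(2):
        fr, fc = rng.uniform(0.5, 2.0, size=2) / max(n_rows, n_cols)
        phase = rng.uniform(0, 2 * np.pi)
        field2d += np.sin(2 * np.pi * (fr * rows + fc * cols) + phase)
    field2d *= amplitude / np.sqrt(2.0)
    return np.broadcast_to(field2d, atlas.grid_shape).copy()


def _lesion_mask(atlas: AtlasGeometry, spec: LesionSpec, rng: np.random.Generator) -> np.ndarray:
    """Disc of lesion voxels around a random in-mask seed voxel of the target wedge."""
    labels = partition_subregions(atlas)
    in_wedge = (labels.labels == spec.region) & (atlas.femur_mask | atlas.acetab_mask)
    coords = np.argwhere(in_wedge)
    if coords.size == 0:
        return np.zeros(atlas.grid_shape, dtype=bool)
    center = coords[rng.integers(len(coords))]
    _, n_rows, n_cols = atlas.grid_shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    disc = np.hypot(rows - center[1], cols - center[2]) <= spec.radius_vox
    return np.broadcast_to(disc, atlas.grid_shape) & (atlas.femur_mask | atlas.acetab_mask)


def simulate_truth_maps(
    atlas: AtlasGeometry,
    config: CohortConfig,
    participant: int,
    hip: int = 0,
    timepoint: int = 0,
    covariates: pd.DataFrame | None = None,
) -> dict[Contrast, RelaxationMap]:
    """Ground-truth relaxation maps of one hip at one timepoint.

    value = base + participant offset + smooth field + covariate effects + lesion.
    The participant offset, field and lesion are constant over timepoints, so yearly
    change comes only from the covariate terms.  Fully reproducible from
    (config.seed, participant, hip, timepoint).
    """
    if covariates is None:
        covariates = draw_covariates(config)
    cov = covariates[
        (covariates["participant_id"] == f"P{participant:02d}")
        & (covariates["acq_year"] == timepoint)
    ]
    if cov.empty:
        raise InputError(f"no covariates for participant {participant}, year {timepoint}")
    cov = cov.iloc[0]

    unit = participant * config.hips_per_participant + hip
    mask = atlas.femur_mask | atlas.acetab_mask
    out: dict[Contrast, RelaxationMap] = {}
    for contrast, base in config.base_mean_ms.items():
        contrast = Contrast(contrast)
        ck = _CONTRAST_KEY[contrast]
        subj_rng = _rng(config.seed, _T_SUBJECT, unit, ck)
        offset = float(subj_rng.normal(0.0, config.between_subject_sd_ms)) if config.between_subject_sd_ms else 0.0
        fld = _smooth_field(atlas, config.spatial_sd_ms, _rng(config.seed, _T_FIELD, unit, ck))

        value = np.full(atlas.grid_shape, np.nan)
        v = (
            base
            + offset
            + config.bmi_slope_ms * (float(cov["bmi"]) - config.bmi_ref)
            + config.sex_offset_ms * (1.0 if cov["sex"] == "F" else 0.0)
            + config.year_slope_ms * float(timepoint)
            + config.kl_slope_ms * float(cov["kl_score"])
        )
        value[mask] = v + fld[mask]

        if config.lesion.prevalence > 0:
            lesion_rng = _rng(config.seed, _T_LESION, unit)
            if lesion_rng.random() < config.lesion.prevalence:
                lm = _lesion_mask(atlas, config.lesion, lesion_rng)
                value[lm] += config.lesion.elevation_ms

        out[contrast] = RelaxationMap(
            values=value,
            amplitudes=np.where(mask, 100.0, np.nan),
            valid=mask.copy(),
            contrast=contrast,
        )
    return out


def apply_scanner_model(
    rmap: RelaxationMap, scanner: ScannerModel, seed: int, stream: tuple[int, ...] = ()
) -> RelaxationMap:
    """Observe a truth map through a scanner: affine bias plus Gaussian voxel noise.

    Validity is preserved; the caller re-applies the contrast upper threshold."""
    rng = _rng(seed, _T_SCANNER, *stream)
    out = rmap.copy()
    noise = rng.normal(0.0, scanner.noise_sd_ms, size=rmap.grid_shape) if scanner.noise_sd_ms else 0.0
    observed = scanner.scale * rmap.values + scanner.offset_ms + noise
    out.values = np.where(rmap.valid, observed, np.nan)
    return out


def simulate_echo_series(
    truth_map: RelaxationMap,
    times_ms=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EchoSeries:
    """Forward-simulate a multi-preparation-time series from a truth map.

    signals = S0 * exp(-t/T) + Gaussian noise, floored at zero; voxels that are
    invalid or have T <= 0 produce zero signal.
    """
    if times_ms is None:
        times_ms = DEFAULT_TIMES_MS[truth_map.contrast]
    times = np.asarray(times_ms, dtype=float)
    rng = _rng(seed, _T_ECHO)
    gen = truth_map.valid & (truth_map.values > 0)
    t_safe = np.where(gen, truth_map.values, 1.0)
    amp = np.where(gen, truth_map.amplitudes, 0.0)
    signals = amp[..., None] * np.exp(-times[None, None, None, :] / t_safe[..., None])
    signals[~gen] = 0.0
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    signals = np.clip(signals, 0.0, None)
    return EchoSeries(signals=signals, times_ms=times, contrast=truth_map.contrast)


def _unit_ids(config: CohortConfig) -> list[tuple[int, int, str]]:
    sides = ["L", "R", "L2", "R2"]
    out = []
    for p in range(config.n_participants):
        for h in range(config.hips_per_participant):
            out.append((p, h, f"P{p:02d}_{sides[h]}"))
    return out


def simulate_two_scanner_study(
    config: CohortConfig,
    scanner1: ScannerModel,
    scanner2: ScannerModel,
    atlas: AtlasGeometry | None = None,
    contrast: Contrast = Contrast.T1RHO,
) -> tuple[VoxelStack, VoxelStack, dict]:
    """Same cohort observed on two scanners: the calibration-study design.

    Every hip is a paired unit (8 participants x 2 hips = 16 paired hips by
    default).  Each unit's truth map is observed through both scanner models with
    independent voxel noise; the contrast's upper threshold is applied to the
    observations.  Returns the two matched stacks and the truth maps.
    """
    if atlas is None:
        atlas = make_atlas()
    covs = draw_covariates(config)
    maps1, maps2, ids, truths = [], [], [], {}
    for p, h, uid in _unit_ids(config):
        truth = simulate_truth_maps(atlas, config, p, hip=h, timepoint=0, covariates=covs)[contrast]
        unit = p * config.hips_per_participant + h
        obs1 = apply_scanner_model(truth, scanner1, config.seed, stream=(unit, 1))
        obs2 = apply_scanner_model(truth, scanner2, config.seed, stream=(unit, 2))
        maps1.append(apply_upper_threshold(obs1))
        maps2.append(apply_upper_threshold(obs2))
        ids.append(uid)
        truths[uid] = truth
    return (
        VoxelStack(maps1, list(ids), group_tag=scanner1.id),
        VoxelStack(maps2, list(ids), group_tag=scanner2.id),
        {"atlas": atlas, "truth_maps": truths, "covariates": covs},
    )


def simulate_lme_table(
    n_participants: int = 18,
    hips_per_participant: int = 2,
    timepoints: int = 5,
    coefficients: dict | None = None,
    random_intercept_sd: float = 2.0,
    residual_sd: float = 1.0,
    seed: int = 0,
    cartilage: str = "femur",
    region: str = "WHOLE",
    contrast: str = "t1rho",
) -> tuple[pd.DataFrame, dict]:
    """Tabular cohort with a known linear generating model, for trajectory-model
    recovery studies.

    The outcome of hip j of participant i at year t is
    ``sum_k coef_k * x_k + b_i + e`` with ``b_i ~ N(0, random_intercept_sd^2)`` and
    ``e ~ N(0, residual_sd^2)``.  Coefficient keys match the model's design terms
    (acq_year, sex_female, age, kl_score, bmi); defaults are bmi=1.2 ms per kg/m^2
    and acq_year=0.9 ms/year with all others zero.  Returns the long table and the
    generating coefficients.
    """
    if coefficients is None:
        coefficients = {"bmi": 1.2, "acq_year": 0.9}
    coefs = {k: float(coefficients.get(k, 0.0)) for k in ["acq_year", "sex_female", "age", "kl_score", "bmi"]}
    cfg = CohortConfig(
        n_participants=n_participants,
        hips_per_participant=hips_per_participant,
        timepoints=timepoints,
        seed=seed,
    )
    covs = draw_covariates(cfg)
    rng = _rng(seed, _T_LME)
    intercepts = rng.normal(0.0, random_intercept_sd, size=n_participants)
    rows = []
    sides = ["L", "R", "L2", "R2"]
    for p in range(n_participants):
        pid = f"P{p:02d}"
        for h in range(hips_per_participant):
            for year in range(timepoints):
                c = covs[(covs["participant_id"] == pid) & (covs["acq_year"] == year)].iloc[0]
                x = {
                    "acq_year": float(year),
                    "sex_female": 1.0 if c["sex"] == "F" else 0.0,
                    "age": float(c["age"]),
                    "kl_score": float(c["kl_score"]),
                    "bmi": float(c["bmi"]),
                }
                y = sum(coefs[k] * x[k] for k in coefs) + intercepts[p] + rng.normal(0.0, residual_sd)
                rows.append(
                    dict(
                        participant_id=pid,
                        hip_side=sides[h],
                        acq_year=year,
                        age=x["age"],
                        sex=c["sex"],
                        bmi=x["bmi"],
                        kl_score=int(c["kl_score"]),
                        cartilage=cartilage,
                        region=region,
                        contrast=contrast,
                        mean_ms=float(y),
                    )
                )
    table = pd.DataFrame(rows)
    return table, {"coefficients": coefs, "random_intercept_sd": random_intercept_sd, "residual_sd": residual_sd}


def simulate_longitudinal_cohort(
    config: CohortConfig,
    scanner_schedule: dict[int, ScannerModel],
    atlas: AtlasGeometry | None = None,
    min_pixels: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Full longitudinal study: truth maps observed per year through the scheduled
    scanner, reduced to region means and joined with covariates.

    ``scanner_schedule`` maps each acquisition year to its scanner model — e.g.
    years 0-3 on one scanner and year 4 on another, the design whose bias the
    calibration stage removes.  Returns the long table plus the generating truth
    (covariates, effect sizes, schedule, atlas and per-year maps).
    """
    if atlas is None:
        atlas = make_atlas()
    for year in range(config.timepoints):
        if year not in scanner_schedule:
            raise InputError(f"scanner_schedule is missing year {year}")
    covs = draw_covariates(config)
    labels = filter_small_subregions(partition_subregions(atlas), min_pixels=min_pixels)
    rows = []
    observed_maps: dict[tuple, dict[Contrast, RelaxationMap]] = {}
    for p, h, uid in _unit_ids(config):
        unit = p * config.hips_per_participant + h
        side = uid.split("_")[1]
        for year in range(config.timepoints):
            truths = simulate_truth_maps(atlas, config, p, hip=h, timepoint=year, covariates=covs)
            per_contrast = {}
            for contrast, truth in truths.items():
                obs = apply_scanner_model(
                    truth, scanner_schedule[year], config.seed, stream=(unit, 10 + year, _CONTRAST_KEY[contrast])
                )
                obs = apply_upper_threshold(obs)
                per_contrast[contrast] = obs
                means = region_mean(obs, labels)
                means.insert(0, "participant_id", f"P{p:02d}")
                means.insert(1, "hip_side", side)
                means.insert(2, "acq_year", year)
                means.insert(3, "contrast", contrast.value)
                rows.append(means)
            observed_maps[(uid, year)] = per_contrast
    region_means = pd.concat(rows, ignore_index=True)
    from .longitudinal import build_long_table

    table, report = build_long_table(region_means, covs)
    truth = {
        "atlas": atlas,
        "labels": labels,
        "covariates": covs,
        "schedule": {y: s for y, s in scanner_schedule.items()},
        "effects": {
            "bmi_slope_ms": config.bmi_slope_ms,
            "year_slope_ms": config.year_slope_ms,
            "sex_offset_ms": config.sex_offset_ms,
            "kl_slope_ms": config.kl_slope_ms,
        },
        "report": report,
        "observed_maps": observed_maps,
        "region_means": region_means,
    }
    return table, truth
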