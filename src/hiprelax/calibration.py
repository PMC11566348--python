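"""Inter-scanner Z-score calibration of relaxation maps.

A scanner change mid-study shifts and rescales the measured relaxation times.  Given
group statistics (mean, SD) of the same cohort imaged on both scanners, a voxel value
from the target scanner is standardized against the target scanner's statistics,
clamped to +/-4 standard scores, and re-expressed in the reference scanner's
distribution:

    z          = clip((T_target - mean_target) / sd_target, -4, +4)
    T_calib    = z * sd_reference + mean_reference

Statistics may be per-voxel (computed across subjects at each atlas voxel, the
default) or global (one scalar mean/SD pooled over all valid voxels and subjects).
When the scanner difference is an affine map of the underlying tissue value, this
transform removes it exactly.

The direction above maps target-scanner data into the reference scanner's space — the
direction a longitudinal study needs when a late timepoint is acquired on a new
scanner.  The reverse mapping (express reference data in the target scanner's space)
is obtained by swapping the two statistics arguments.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyDataError, InputError
from .relaxometry import RelaxationMap, apply_upper_threshold
from .vbr import VoxelStack

__all__ = [
    "StatsScope",
    "GroupStats",
    "ZMap",
    "compute_group_stats",
    "zscore_map",
    "calibrate_map",
    "DEFAULT_CLAMP",
]

logger = logging.getLogger(__name__)

DEFAULT_CLAMP = 4.0


class StatsScope(str, enum.Enum):
    PER_VOXEL = "per_voxel"
    GLOBAL = "global"


@dataclass
class GroupStats:
    """Group mean/SD of relaxation times, per voxel or global.

    ``mean_map`` and ``sd_map`` are full grids (for GLOBAL scope the scalar is
    broadcast); ``usable`` marks voxels with at least two contributors and a strictly
    positive SD — only there can z-scores be formed.
    """

    mean_map: np.ndarray
    sd_map: np.ndarray
    usable: np.ndarray
    n: int
    scope: StatsScope

    def __post_init__(self) -> None:
        self.mean_map = np.asarray(self.mean_map, dtype=float)
        self.sd_map = np.asarray(self.sd_map, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)
        if not (self.mean_map.shape == self.sd_map.shape == self.usable.shape):
            raise InputError("mean_map, sd_map and usable must share one shape")
        if np.any(self.sd_map[self.usable] <= 0):
            raise InputError("usable voxels must have sd > 0")


@dataclass
class ZMap:
    """Clamped standard-score map; |z| <= clamp wherever defined."""

    z: np.ndarray
    defined: np.ndarray
    clamp: float = DEFAULT_CLAMP


def compute_group_stats(stack: VoxelStack, scope: StatsScope = StatsScope.PER_VOXEL) -> GroupStats:
    """Mean and sample SD (n-1 denominator) of a stack's valid voxel values.

    PER_VOXEL: statistics across subjects at each voxel; voxels with fewer than two
    valid contributors, or zero spread, are flagged unusable.  GLOBAL: one scalar
    mean/SD pooled over every valid voxel of every subject, broadcast over the grid.
    """
    va = stack.values_array()
    ma = stack.valid_array()
    shape = stack.grid_shape
    if scope is StatsScope.GLOBAL:
        pooled = va[ma]
        if pooled.size == 0:
            raise EmptyDataError("GLOBAL stats on a stack with no valid voxels")
        mean = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
        usable = np.full(shape, sd > 0, dtype=bool)
        return GroupStats(
            np.full(shape, mean), np.full(shape, sd), usable, stack.n_subjects, scope
        )

    if stack.n_subjects < 2:
        raise InputError("PER_VOXEL stats need at least two maps")
    count = ma.sum(axis=0)
    denom = np.maximum(count, 1)
    mean = np.where(ma, va, 0.0).sum(axis=0) / denom
    ss = (np.where(ma, va - mean, 0.0) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.maximum(count - 1, 1))
    usable = (count >= 2) & (sd > 0)
    mean = np.where(count > 0, mean, np.nan)
    sd = np.where(count >= 2, sd, np.nan)
    n_flagged = int(np.count_nonzero((count > 0) & ~usable))
    if n_flagged:
        logger.info("%d voxel(s) flagged unusable for z-scoring (n<2 or sd=0)", n_flagged)
    return GroupStats(mean, sd, usable, stack.n_subjects, scope)


def zscore_map(rmap: RelaxationMap, stats: GroupStats, clamp: float = DEFAULT_CLAMP) -> ZMap:
    """Standardize a map against group statistics and clamp to +/-``clamp``.

    Defined only where the map is valid and the statistics are usable; voxels with
    sd = 0 are masked out (and have already been flagged in the stats).
    """
    if stats.mean_map.shape != rmap.grid_shape:
        raise InputError("stats grid does not match the map")
    defined = rmap.valid & stats.usable
    z = np.full(rmap.grid_shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (rmap.values - stats.mean_map) / stats.sd_map
    z[defined] = np.clip(raw[defined], -clamp, clamp)
    n_masked = int(np.count_nonzero(rmap.valid & ~stats.usable))
    if n_masked:
        logger.info("%d valid voxel(s) lacked usable stats; z undefined there", n_masked)
    return ZMap(z=z, defined=defined, clamp=clamp)


def calibrate_map(
    map_target: RelaxationMap,
    stats_target: GroupStats,
    stats_reference: GroupStats,
    clamp: float = DEFAULT_CLAMP,
    reapply_threshold: bool = True,
) -> RelaxationMap:
    """Re-express a target-scanner map in the reference scanner's distribution.

    The value is standardized with the target scanner's statistics, clamped to
    +/-``clamp``, and rescaled with the reference scanner's statistics.  Voxels
    without usable statistics on either side become invalid.  The map's contrast
    upper threshold is re-applied afterwards so out-of-range calibrated values are
    removed, unless ``reapply_threshold`` is False.
    """
    zmap = zscore_map(map_target, stats_target, clamp=clamp)
    ok = zmap.defined & stats_reference.usable
    values = np.full(map_target.grid_shape, np.nan)
    values[ok] = zmap.z[ok] * stats_reference.sd_map[ok] + stats_reference.mean_map[ok]
    out = RelaxationMap(
        values, map_target.amplitudes.copy(), ok, map_target.contrast, np.inf
    )
    if reapply_threshold:
        thr = map_target.upper_threshold_ms if np.isfinite(map_target.upper_threshold_ms) else None
        out = apply_upper_threshold(out, thr)
    return out
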