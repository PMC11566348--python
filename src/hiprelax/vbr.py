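"""Voxel-based relaxometry (VBR): voxel-wise group statistics on aligned map stacks.

All subjects' relaxation maps are assumed registered to one atlas grid; a VoxelStack
collects the per-subject maps of one group (typically one scanner).  Group comparison
is a two-sided paired Student's t-test per voxel between matched stacks, summarized as
a p-map and the percentage of tested voxels significant at a chosen alpha.  No
multiple-comparison correction is applied by default (voxel-wise p < alpha), matching
common VBR practice; an optional Benjamini-Hochberg adjustment is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EmptyDataError, InputError
from .relaxometry import Contrast, RelaxationMap

__all__ = [
    "VoxelStack",
    "PMap",
    "paired_ttest_map",
    "significant_fraction",
    "stack_group_mean",
]

logger = logging.getLogger(__name__)


@dataclass
class VoxelStack:
    """Atlas-aligned per-subject maps for one group.

    ``subject_ids`` identify the paired unit; left and right hips of one participant
    are separate units (e.g. ``"P03_L"``), mirroring how bilateral acquisitions enter
    the voxel-wise comparison.
    """

    maps: list[RelaxationMap]
    subject_ids: list[str]
    group_tag: str = ""

    def __post_init__(self) -> None:
        if not self.maps:
            raise InputError("a VoxelStack needs at least one map")
        if len(self.maps) != len(self.subject_ids):
            raise InputError("maps and subject_ids must be parallel lists")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise InputError("subject_ids must be unique within a stack")
        shape = self.maps[0].grid_shape
        contrast = self.maps[0].contrast
        for m in self.maps:
            if m.grid_shape != shape:
                raise InputError("all maps in a stack must share one grid shape")
            if m.contrast != contrast:
                raise InputError("all maps in a stack must share one contrast")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps[0].grid_shape

    @property
    def contrast(self) -> Contrast:
        return self.maps[0].contrast

    @property
    def n_subjects(self) -> int:
        return len(self.maps)

    def values_array(self) -> np.ndarray:
        """Stacked values, shape (n_subjects, slices, rows, cols)."""
        return np.stack([m.values for m in self.maps])

    def valid_array(self) -> np.ndarray:
        return np.stack([m.valid for m in self.maps])


@dataclass
class PMap:
    """Voxel-wise p-values of a paired comparison.

    ``tested`` marks voxels where the test ran (enough complete pairs); ``p`` and
    ``log10p`` are NaN elsewhere.  ``log10p`` supports the customary logarithmic-scale
    display of VBR p-maps.
    """

    p: np.ndarray
    log10p: np.ndarray
    tested: np.ndarray
    alpha: float = 0.05
    n_zero_variance_shift: int = 0

    def bh_adjusted(self) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values over tested voxels (optional, off the
        main path)."""
        out = np.full_like(self.p, np.nan)
        pv = self.p[self.tested]
        if pv.size:
            out[self.tested] = stats.false_discovery_control(pv, method="bh")
        return out


def _match_stacks(a: VoxelStack, b: VoxelStack) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if set(a.subject_ids) != set(b.subject_ids):
        raise InputError("stacks must contain the same subject_ids for a paired test")
    order = [b.subject_ids.index(s) for s in a.subject_ids]
    va, ma = a.values_array(), a.valid_array()
    vb = np.stack([b.maps[i].values for i in order])
    mb = np.stack([b.maps[i].valid for i in order])
    return va, ma, vb, mb


def paired_ttest_map(a: VoxelStack, b: VoxelStack, n_min: int | None = None, alpha: float = 0.05) -> PMap:
    """Two-sided paired Student's t-test at every voxel between matched stacks.

    Subjects are matched by ``subject_ids`` (order-independent).  At each voxel the
    per-subject differences use only pairs valid in both maps; the voxel is tested
    when at least ``n_min`` complete pairs exist (default: every pair, and never
    fewer than 2).

    Degenerate differences: all-zero differences give p = 1 (no evidence of change);
    zero-variance but nonzero-mean differences (a constant shift) give a p = 0
    sentinel, with an aggregated warning — the t statistic is infinite and the shift
    is unambiguous.
    """
    if a.grid_shape != b.grid_shape:
        raise InputError("stacks must share one grid shape")
    va, ma, vb, mb = _match_stacks(a, b)
    n_subj = va.shape[0]
    if n_min is None:
        n_min = n_subj
    n_min = max(int(n_min), 2)

    pair_ok = ma & mb
    d = np.where(pair_ok, va - vb, 0.0)
    count = pair_ok.sum(axis=0)
    tested = count >= n_min

    denom = np.maximum(count, 1)
    mean_d = d.sum(axis=0) / denom
    ss = (np.where(pair_ok, d - mean_d, 0.0) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd_d = np.sqrt(ss / np.maximum(count - 1, 1))
    mean_d = np.where(tested, mean_d, np.nan)
    sd_d = np.where(tested, sd_d, np.nan)

    p = np.full(a.grid_shape, np.nan)
    zero_var = tested & (sd_d == 0)
    zero_var_null = zero_var & (mean_d == 0)
    zero_var_shift = zero_var & (mean_d != 0)
    p[zero_var_null] = 1.0
    p[zero_var_shift] = 0.0
    n_shift = int(np.count_nonzero(zero_var_shift))
    if n_shift:
        logger.warning(
            "%d voxel(s) with constant nonzero paired difference: p set to 0 sentinel", n_shift
        )

    regular = tested & (sd_d > 0)
    if np.any(regular):
        n_vox = count[regular]
        t = mean_d[regular] / (sd_d[regular] / np.sqrt(n_vox))
        p[regular] = 2.0 * stats.t.sf(np.abs(t), df=n_vox - 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        log10p = np.where(tested, np.log10(p), np.nan)
    return PMap(p=p, log10p=log10p, tested=tested, alpha=alpha, n_zero_variance_shift=n_shift)


def significant_fraction(pmap: PMap, mask: np.ndarray, alpha: float = 0.05) -> float:
    """Percentage of tested voxels inside ``mask`` with p < alpha."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.p.shape:
        raise InputError("mask shape does not match the p-map")
    tested = pmap.tested & mask
    n_tested = int(np.count_nonzero(tested))
    if n_tested == 0:
        raise EmptyDataError("no tested voxels inside the mask")
    n_sig = int(np.count_nonzero(tested & (pmap.p < alpha)))
    return 100.0 * n_sig / n_tested


def stack_group_mean(stack: VoxelStack, min_valid_fraction: float = 0.5) -> RelaxationMap:
    """Voxel-wise mean map of a stack.

    A voxel of the result is valid when it is valid in at least
    ``min_valid_fraction`` of the maps (default: half); its value is the mean over
    the maps where it is valid.
    """
    va = stack.values_array()
    ma = stack.valid_array()
    count = ma.sum(axis=0)
    denom = np.maximum(count, 1)
    mean = np.where(count > 0, np.where(ma, va, 0.0).sum(axis=0) / denom, np.nan)
    amps = np.stack([m.amplitudes for m in stack.maps])
    amp = np.where(count > 0, np.where(ma, amps, 0.0).sum(axis=0) / denom, np.nan)
    valid = count >= min_valid_fraction * stack.n_subjects
    thr = min(m.upper_threshold_ms for m in stack.maps)
    return RelaxationMap(mean, amp, valid, stack.contrast, thr)
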