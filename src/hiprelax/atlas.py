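"""Atlas-space cartilage geometry: angular subregions and region means.

The femoral and acetabular cartilage masks live on a common atlas voxel grid.  Each
sagittal slice is partitioned into eight 45-degree wedges about the femoral-head
center, measured from a reference line drawn parallel to the femoral neck.  Wedge k
covers the half-open angular interval [(k-1)*45, k*45) degrees counterclockwise from
the reference line, so a voxel exactly on a wedge boundary belongs to the
higher-numbered wedge.  Angles are measured in the displayed image plane: x increases
with column index and y points up the image (decreasing row index).

Anatomically the retained wedges are R2 (posterior) through R6 (anterior) for the
femur and R2-R5 for the acetabulum; wedges whose total voxel count across the analyzed
slices falls below a minimum (default 50) are dropped from the retained sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import EmptyDataError, InputError
from .relaxometry import RelaxationMap

__all__ = [
    "AtlasGeometry",
    "SubregionLabels",
    "FEMUR",
    "ACETABULUM",
    "CANDIDATE_REGIONS",
    "partition_subregions",
    "filter_small_subregions",
    "select_central_slices",
    "region_mean",
    "WHOLE",
]

logger = logging.getLogger(__name__)

FEMUR = "femur"
ACETABULUM = "acetab"
WHOLE = "WHOLE"

#: Candidate subregions considered for analysis, before the small-region filter.
CANDIDATE_REGIONS: dict[str, frozenset[int]] = {
    FEMUR: frozenset({2, 3, 4, 5, 6}),
    ACETABULUM: frozenset({2, 3, 4, 5}),
}


@dataclass
class AtlasGeometry:
    """Atlas voxel grid with head center, reference-line angle and cartilage masks.

    ``head_center`` is one shared (row, col) per hip, used for every slice — the
    reference atlas treats the femoral head as a single sphere.  ``femur_mask`` and
    ``acetab_mask`` must be disjoint boolean grids of shape ``grid_shape``.
    """

    grid_shape: tuple[int, int, int]
    head_center: tuple[float, float]
    reference_angle_deg: float
    femur_mask: np.ndarray
    acetab_mask: np.ndarray

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.femur_mask = np.asarray(self.femur_mask, dtype=bool)
        self.acetab_mask = np.asarray(self.acetab_mask, dtype=bool)
        if self.femur_mask.shape != self.grid_shape or self.acetab_mask.shape != self.grid_shape:
            raise InputError("masks must match grid_shape")
        if np.any(self.femur_mask & self.acetab_mask):
            raise InputError("femur and acetabulum masks must be disjoint")
        r, c = self.head_center
        if not (0 <= r < self.grid_shape[1] and 0 <= c < self.grid_shape[2]):
            raise InputError("head_center must lie inside the in-plane grid")

    def mask(self, cartilage: str) -> np.ndarray:
        if cartilage == FEMUR:
            return self.femur_mask
        if cartilage == ACETABULUM:
            return self.acetab_mask
        raise InputError(f"unknown cartilage {cartilage!r}")


@dataclass
class SubregionLabels:
    """Wedge labels 1..8 per voxel (0 = background), with retained-region sets.

    One label grid covers both cartilages; the geometry's disjoint masks identify
    which cartilage an in-mask voxel belongs to.
    """

    labels: np.ndarray
    geom: AtlasGeometry
    retained: dict[str, frozenset[int]]
    n_center_excluded: int = 0

    def counts(self, cartilage: str) -> dict[int, int]:
        """Total voxel count per wedge (1..8) within one cartilage mask, all slices."""
        mask = self.geom.mask(cartilage)
        lab = self.labels[mask]
        return {k: int(np.count_nonzero(lab == k)) for k in range(1, 9)}


def voxel_angles_deg(grid_shape, head_center, reference_angle_deg: float) -> np.ndarray:
    """In-plane angle (degrees, [0, 360)) of every voxel about the head center,
    counterclockwise from the reference line.  Identical for every slice."""
    _, n_rows, n_cols = grid_shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    dx = cols - head_center[1]
    dy = -(rows - head_center[0])  # y up in the displayed image
    theta = np.degrees(np.arctan2(dy, dx))
    return np.mod(theta - reference_angle_deg, 360.0)


def partition_subregions(geom: AtlasGeometry) -> SubregionLabels:
    """Assign every in-mask voxel to one of eight 45-degree wedges.

    Wedge k is the half-open interval [(k-1)*45, k*45) degrees counterclockwise from
    the reference line.  A voxel exactly at the head center has no defined angle; it
    is left unlabeled and counted.
    """
    combined = geom.femur_mask | geom.acetab_mask
    if not combined.any():
        raise EmptyDataError("both cartilage masks are empty")
    theta = voxel_angles_deg(geom.grid_shape, geom.head_center, geom.reference_angle_deg)
    wedge = (np.floor(theta / 45.0).astype(int) + 1).clip(1, 8)

    _, n_rows, n_cols = geom.grid_shape
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    at_center = (rows == geom.head_center[0]) & (cols == geom.head_center[1])

    labels = np.zeros(geom.grid_shape, dtype=np.int16)
    labels[combined] = np.broadcast_to(wedge, geom.grid_shape)[combined]
    center3d = np.broadcast_to(at_center, geom.grid_shape) & combined
    n_center = int(np.count_nonzero(center3d))
    if n_center:
        labels[center3d] = 0
        logger.warning("%d in-mask voxel(s) at the head center excluded (angle undefined)", n_center)
    return SubregionLabels(
        labels=labels,
        geom=geom,
        retained={c: frozenset(s) for c, s in CANDIDATE_REGIONS.items()},
        n_center_excluded=n_center,
    )


def filter_small_subregions(labels: SubregionLabels, min_pixels: int = 50) -> SubregionLabels:
    """Drop retained subregions whose total voxel count over all slices is below
    ``min_pixels`` (strict: a region with exactly ``min_pixels`` voxels is kept)."""
    new_retained: dict[str, frozenset[int]] = {}
    for cartilage, regions in labels.retained.items():
        counts = labels.counts(cartilage)
        kept = frozenset(r for r in regions if counts[r] >= min_pixels)
        dropped = regions - kept
        if dropped:
            logger.info("%s: dropped subregions %s (< %d voxels)", cartilage, sorted(dropped), min_pixels)
        new_retained[cartilage] = kept
    return replace(labels, retained=new_retained)


def select_central_slices(rmap: RelaxationMap, center_index: int, n: int = 4) -> RelaxationMap:
    """Restrict a map's validity to the ``n`` slices centered at ``center_index``.

    For even ``n`` the asymmetric span is resolved toward lower slice indices:
    60 slices, center 30, n=4 selects slices 28..31.
    """
    n_slices = rmap.slice_count
    if not (0 <= center_index < n_slices):
        raise InputError(f"center_index {center_index} out of range for {n_slices} slices")
    if n > n_slices:
        raise InputError(f"cannot select {n} slices from a {n_slices}-slice map")
    start = center_index - n // 2
    start = min(max(start, 0), n_slices - n)
    out = rmap.copy()
    keep = np.zeros(n_slices, dtype=bool)
    keep[start : start + n] = True
    out.valid &= keep[:, None, None]
    return out


def region_mean(rmap: RelaxationMap, labels: SubregionLabels) -> pd.DataFrame:
    """Mean relaxation time per retained subregion and per whole cartilage.

    Returns a tidy frame with columns ``cartilage``, ``region`` ("R2".."R8" or
    "WHOLE"), ``mean_ms`` and ``n_voxels``.  Means use valid voxels only; a region
    with no valid voxels gets ``mean_ms = NaN`` and ``n_voxels = 0``.  The WHOLE mean
    averages all valid in-mask voxels directly, not the subregion means.
    """
    if rmap.grid_shape != labels.geom.grid_shape:
        raise InputError("map and atlas grids do not match")
    rows = []
    for cartilage in (FEMUR, ACETABULUM):
        mask = labels.geom.mask(cartilage)
        valid = mask & rmap.valid
        vals = rmap.values[valid]
        rows.append(
            dict(
                cartilage=cartilage,
                region=WHOLE,
                mean_ms=float(np.mean(vals)) if vals.size else np.nan,
                n_voxels=int(vals.size),
            )
        )
        for r in sorted(labels.retained[cartilage]):
            sel = valid & (labels.labels == r)
            vals = rmap.values[sel]
            rows.append(
                dict(
                    cartilage=cartilage,
                    region=f"R{r}",
                    mean_ms=float(np.mean(vals)) if vals.size else np.nan,
                    n_voxels=int(vals.size),
                )
            )
    return pd.DataFrame(rows, columns=["cartilage", "region", "mean_ms", "n_voxels"])
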