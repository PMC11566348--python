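"""Angular subregion geometry: wedge labels, filtering, slice selection, means."""

import numpy as np
import pandas as pd
import pytest

from hiprelax import (
    ACETABULUM,
    FEMUR,
    Contrast,
    InputError,
    RelaxationMap,
    filter_small_subregions,
    make_atlas,
    partition_subregions,
    region_mean,
    select_central_slices,
)
from hiprelax.atlas import voxel_angles_deg
from tests.conftest import constant_map


class TestPartition:
    def test_labels_match_angle_formula(self, small_atlas):
        labels = partition_subregions(small_atlas)
        theta = voxel_angles_deg(
            small_atlas.grid_shape, small_atlas.head_center, small_atlas.reference_angle_deg
        )
        expected = np.floor(theta / 45.0).astype(int) + 1
        mask = small_atlas.femur_mask | small_atlas.acetab_mask
        assert np.array_equal(labels.labels[mask], np.broadcast_to(expected, mask.shape)[mask])

    def test_wedge_boundary_half_open(self):
        # a voxel at exactly 45 degrees falls in wedge 2
        atlas = make_atlas(
            grid_shape=(1, 65, 65), head_center=(32.0, 32.0),
            femur_radii=(11.0, 13.0), acetab_radii=(15.0, 17.0),
        )
        labels = partition_subregions(atlas)
        # (row, col) = (32-9, 32+9) lies at 45 deg, radius 12.7 -> femur band
        assert labels.labels[0, 32 - 9, 32 + 9] == 2
        # 0 degrees -> wedge 1; 90 degrees -> wedge 3
        assert labels.labels[0, 32, 32 + 12] == 1
        assert labels.labels[0, 32 - 12, 32] == 3

    def test_equal_wedge_areas_on_annulus(self):
        atlas = make_atlas(
            grid_shape=(1, 64, 64), head_center=(31.5, 31.5),
            femur_radii=(20.0, 24.0), acetab_radii=(26.0, 27.0),
        )
        counts = partition_subregions(atlas).counts(FEMUR)
        values = np.array(list(counts.values()))
        assert np.all(np.abs(values - values.mean()) / values.mean() <= 0.05)

    def test_rotation_equivariance(self):
        atlas = make_atlas(
            grid_shape=(2, 65, 65), head_center=(32.0, 32.0),
            femur_radii=(11.0, 13.0), acetab_radii=(15.0, 17.0),
        )
        base = partition_subregions(atlas).labels
        rotated_atlas = make_atlas(
            grid_shape=(2, 65, 65), head_center=(32.0, 32.0),
            femur_radii=(11.0, 13.0), acetab_radii=(15.0, 17.0),
            reference_angle_deg=90.0,
        )
        rotated = partition_subregions(rotated_atlas).labels
        expected = np.stack([np.rot90(base[s]) for s in range(base.shape[0])])
        assert np.array_equal(rotated, expected)

    def test_partition_covers_masks(self, small_atlas):
        labels = partition_subregions(small_atlas)
        mask = small_atlas.femur_mask | small_atlas.acetab_mask
        assert np.all(labels.labels[mask] > 0)
        assert np.all(labels.labels[~mask] == 0)
        n_in = int(mask.sum()) - labels.n_center_excluded
        assert int((labels.labels > 0).sum()) == n_in


class TestFilterSmall:
    def test_boundary_strict(self, small_atlas):
        labels = partition_subregions(small_atlas)
        counts = labels.counts(FEMUR)
        # with min_pixels just above the smallest wedge, that wedge is dropped;
        # exactly at the smallest count, it is retained
        smallest_region = min((r for r in labels.retained[FEMUR]), key=lambda r: counts[r])
        n = counts[smallest_region]
        kept = filter_small_subregions(labels, min_pixels=n)
        assert smallest_region in kept.retained[FEMUR]
        dropped = filter_small_subregions(labels, min_pixels=n + 1)
        assert smallest_region not in dropped.retained[FEMUR]

    def test_identity_when_all_large(self, small_atlas):
        labels = partition_subregions(small_atlas)
        kept = filter_small_subregions(labels, min_pixels=1)
        assert kept.retained == labels.retained
        assert kept.retained[FEMUR] == frozenset({2, 3, 4, 5, 6})
        assert kept.retained[ACETABULUM] == frozenset({2, 3, 4, 5})


class TestSelectCentralSlices:
    def _map(self, n_slices):
        shape = (n_slices, 4, 4)
        return RelaxationMap(
            np.full(shape, 30.0), np.full(shape, 100.0), np.ones(shape, dtype=bool), Contrast.T1RHO
        )

    @pytest.mark.parametrize(
        "n_slices,center,n,expected",
        [(60, 30, 4, {28, 29, 30, 31}), (20, 10, 4, {8, 9, 10, 11}), (5, 2, 5, {0, 1, 2, 3, 4})],
    )
    def test_selection(self, n_slices, center, n, expected):
        out = select_central_slices(self._map(n_slices), center, n)
        assert set(np.where(out.valid.any(axis=(1, 2)))[0]) == expected

    def test_errors(self):
        with pytest.raises(InputError):
            select_central_slices(self._map(10), 10, 4)
        with pytest.raises(InputError):
            select_central_slices(self._map(3), 1, 4)


class TestRegionMean:
    def test_simple_mean_and_missing(self, small_atlas):
        labels = filter_small_subregions(partition_subregions(small_atlas))
        rmap = constant_map(small_atlas, np.nan)
        rmap.valid[:] = False
        # two valid voxels in femur wedge 3
        r3 = (labels.labels == 3) & small_atlas.femur_mask
        idx = np.argwhere(r3)[:2]
        for (s, r, c), v in zip(idx, (30.0, 40.0)):
            rmap.values[s, r, c] = v
            rmap.valid[s, r, c] = True
        means = region_mean(rmap, labels)
        fem = means[means.cartilage == FEMUR].set_index("region")
        assert fem.loc["R3", "mean_ms"] == pytest.approx(35.0)
        assert fem.loc["R3", "n_voxels"] == 2
        # a fully invalid region is missing, not zero
        assert np.isnan(fem.loc["R4", "mean_ms"])
        assert fem.loc["R4", "n_voxels"] == 0

    def test_constant_map(self, small_atlas):
        labels = filter_small_subregions(partition_subregions(small_atlas))
        means = region_mean(constant_map(small_atlas, 42.0), labels)
        assert np.allclose(means["mean_ms"], 42.0)

    def test_whole_is_count_weighted_mean_of_all_wedges(self, small_atlas):
        rng = np.random.default_rng(3)
        labels = partition_subregions(small_atlas)
        rmap = constant_map(small_atlas, 0.0)
        rmap.values[rmap.valid] = rng.uniform(20, 60, int(rmap.valid.sum()))
        means = region_mean(rmap, labels)
        for cartilage in (FEMUR, ACETABULUM):
            mask = small_atlas.mask(cartilage) & rmap.valid
            whole = means[(means.cartilage == cartilage) & (means.region == "WHOLE")]["mean_ms"].iloc[0]
            # direct count-weighted mean over the full 8-wedge partition
            acc, n = 0.0, 0
            for k in range(1, 9):
                sel = mask & (labels.labels == k)
                acc += rmap.values[sel].sum()
                n += int(sel.sum())
            assert whole == pytest.approx(acc / n)

    def test_shape_mismatch(self, small_atlas):
        labels = partition_subregions(small_atlas)
        bad = RelaxationMap(
            np.zeros((1, 4, 4)), np.zeros((1, 4, 4)), np.ones((1, 4, 4), dtype=bool), Contrast.T1RHO
        )
        with pytest.raises(InputError):
            region_mean(bad, labels)
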