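"""Synthetic cohort generator: geometry, truth maps, scanner models, study designs."""

import numpy as np
import pytest

from hiprelax import (
    CohortConfig,
    Contrast,
    InputError,
    LesionSpec,
    ScannerModel,
    apply_scanner_model,
    draw_covariates,
    fit_map,
    make_atlas,
    partition_subregions,
    simulate_echo_series,
    simulate_longitudinal_cohort,
    simulate_truth_maps,
    simulate_two_scanner_study,
)
from hiprelax.longitudinal import validate_long_table


def quiet_config(**kw):
    defaults = dict(between_subject_sd_ms=0.0, spatial_sd_ms=0.0, seed=0)
    defaults.update(kw)
    return CohortConfig(**defaults)


SMALL_ATLAS_KW = dict(
    grid_shape=(2, 64, 64), head_center=(32.0, 32.0),
    femur_radii=(11.0, 13.0), acetab_radii=(15.0, 17.0),
)


class TestMakeAtlas:
    def test_default_atlas_has_no_filtered_wedges(self):
        atlas = make_atlas()
        labels = partition_subregions(atlas)
        for cartilage in ("femur", "acetab"):
            assert all(n >= 50 for n in labels.counts(cartilage).values())

    def test_masks_disjoint_with_gap(self):
        atlas = make_atlas()
        assert not np.any(atlas.femur_mask & atlas.acetab_mask)

    def test_overlapping_bands_error(self):
        with pytest.raises(InputError):
            make_atlas(femur_radii=(20.0, 24.0), acetab_radii=(24.5, 28.0))

    def test_empty_band_error(self):
        with pytest.raises(InputError):
            make_atlas(femur_radii=(23.0, 20.0))

    def test_reference_rotation_shifts_wedge_labels_by_one(self):
        base = partition_subregions(make_atlas(**SMALL_ATLAS_KW)).labels
        shifted = partition_subregions(make_atlas(**SMALL_ATLAS_KW, reference_angle_deg=45.0)).labels
        in_mask = base > 0
        expected = (base[in_mask] - 2) % 8 + 1  # one wedge down, wrapping 1 -> 8
        assert np.array_equal(shifted[in_mask], expected)


class TestTruthMaps:
    def test_all_effects_zero_gives_constant_base(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        maps = simulate_truth_maps(atlas, quiet_config(), participant=0)
        t1 = maps[Contrast.T1RHO]
        assert np.allclose(t1.values[t1.valid], 35.0)
        t2 = maps[Contrast.T2]
        assert np.allclose(t2.values[t2.valid], 28.0)

    def test_year_slope_shifts_mean_linearly(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        cfg = quiet_config(year_slope_ms=0.9, timepoints=5)
        m0 = simulate_truth_maps(atlas, cfg, 0, timepoint=0)[Contrast.T1RHO]
        m4 = simulate_truth_maps(atlas, cfg, 0, timepoint=4)[Contrast.T1RHO]
        diff = m4.values[m4.valid] - m0.values[m0.valid]
        assert np.allclose(diff, 3.6)

    def test_lesion_elevation(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        cfg = quiet_config(lesion=LesionSpec(region=3, radius_vox=3.0, elevation_ms=8.0, prevalence=1.0))
        m = simulate_truth_maps(atlas, cfg, 0)[Contrast.T1RHO]
        vals = m.values[m.valid]
        lesion_vals = vals[vals > 35.0]
        assert lesion_vals.size > 0
        assert np.allclose(lesion_vals, 43.0)

    def test_reproducible_from_seed(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        cfg = CohortConfig(seed=9)
        a = simulate_truth_maps(atlas, cfg, 1)[Contrast.T1RHO]
        b = simulate_truth_maps(atlas, cfg, 1)[Contrast.T1RHO]
        assert np.array_equal(a.values[a.valid], b.values[b.valid])


class TestScannerModel:
    def test_identity(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        truth = simulate_truth_maps(atlas, quiet_config(), 0)[Contrast.T1RHO]
        obs = apply_scanner_model(truth, ScannerModel(1.0, 0.0, 0.0), seed=0)
        assert np.array_equal(obs.values[obs.valid], truth.values[truth.valid])

    def test_affine(self):
        atlas = make_atlas(**SMALL_ATLAS_KW)
        truth = simulate_truth_maps(atlas, quiet_config(base_mean_ms={Contrast.T1RHO: 30.0}), 0)[Contrast.T1RHO]
        obs = apply_scanner_model(truth, ScannerModel(1.1, 2.0, 0.0), seed=0)
        assert np.allclose(obs.values[obs.valid], 35.0)

    def test_noise_sd_calibrated(self):
        shape = (1, 100, 100)
        from hiprelax import RelaxationMap

        truth = RelaxationMap(
            np.full(shape, 35.0), np.full(shape, 100.0), np.ones(shape, bool), Contrast.T1RHO
        )
        obs = apply_scanner_model(truth, ScannerModel(1.0, 0.0, 1.5), seed=12)
        resid = obs.values - 35.0
        assert 1.4 <= resid.std() <= 1.6

    def test_invalid_parameters(self):
        with pytest.raises(InputError):
            ScannerModel(scale=0.0)
        with pytest.raises(InputError):
            ScannerModel(noise_sd_ms=-1.0)


class TestEchoSeries:
    def test_noiseless_roundtrip(self):
        atlas = make_atlas(grid_shape=(1, 32, 32), head_center=(16.0, 16.0),
                           femur_radii=(6.0, 7.0), acetab_radii=(9.0, 10.0))
        truth = simulate_truth_maps(atlas, quiet_config(), 0)[Contrast.T1RHO]
        series = simulate_echo_series(truth)
        refit = fit_map(series, truth.valid)
        assert np.all(np.abs(refit.values[refit.valid] - truth.values[truth.valid]) < 1e-6)

    def test_nonpositive_t_voxels_emit_zero_signal(self):
        from hiprelax import RelaxationMap

        v = np.array([[[35.0, 0.0]]])
        truth = RelaxationMap(v, np.full_like(v, 100.0), np.ones_like(v, bool), Contrast.T1RHO)
        series = simulate_echo_series(truth)
        assert np.all(series.signals[0, 0, 1] == 0.0)
        assert np.all(series.signals[0, 0, 0] > 0.0)

    def test_noisy_fit_rmse(self):
        shape = (1, 20, 50)  # 1000 voxels
        from hiprelax import RelaxationMap

        truth = RelaxationMap(
            np.full(shape, 35.0), np.full(shape, 100.0), np.ones(shape, bool), Contrast.T1RHO
        )
        series = simulate_echo_series(truth, noise_sd=2.0, seed=13)  # 2% of S0
        refit = fit_map(series, truth.valid)
        rmse = np.sqrt(np.mean((refit.values[refit.valid] - 35.0) ** 2))
        assert rmse < 2.0


class TestStudyDesigns:
    def test_two_scanner_study_determinism_and_pairing(self):
        cfg = CohortConfig(n_participants=2, seed=3)
        s1, s2 = ScannerModel(id="a"), ScannerModel(1.1, 2.0, 1.0, "b")
        atlas = make_atlas(**SMALL_ATLAS_KW)
        a1, a2, _ = simulate_two_scanner_study(cfg, s1, s2, atlas=atlas)
        b1, b2, _ = simulate_two_scanner_study(cfg, s1, s2, atlas=atlas)
        assert a1.subject_ids == a2.subject_ids == b1.subject_ids
        assert len(a1.maps) == 4  # 2 participants x 2 hips as paired units
        for m_a, m_b in zip(a1.maps + a2.maps, b1.maps + b2.maps):
            assert np.array_equal(m_a.values[m_a.valid], m_b.values[m_b.valid])

    def test_longitudinal_cohort_feeds_downstream_contracts(self):
        cfg = CohortConfig(n_participants=3, timepoints=3, seed=4, year_slope_ms=0.9)
        schedule = {y: ScannerModel(id="s1") for y in range(3)}
        table, truth = simulate_longitudinal_cohort(cfg, schedule, atlas=make_atlas(**SMALL_ATLAS_KW), min_pixels=10)
        validate_long_table(table)  # passes all long-table preconditions
        whole = table[(table.region == "WHOLE") & (table.cartilage == "femur") & (table.contrast == "t1rho")]
        yearly = whole.groupby("acq_year")["mean_ms"].mean()
        diffs = np.diff(yearly.values)
        assert np.all(diffs > 0.5)  # linear upward trend ~0.9 ms/year

    def test_scanner_switch_induces_jump(self):
        base = 35.0
        cfg = CohortConfig(n_participants=3, timepoints=3, seed=4, between_subject_sd_ms=0.0, spatial_sd_ms=0.0)
        schedule = {0: ScannerModel(id="s1"), 1: ScannerModel(id="s1"), 2: ScannerModel(1.1, 2.0, 0.0, "s2")}
        table, _ = simulate_longitudinal_cohort(cfg, schedule, atlas=make_atlas(**SMALL_ATLAS_KW), min_pixels=10)
        whole = table[(table.region == "WHOLE") & (table.cartilage == "femur") & (table.contrast == "t1rho")]
        yearly = whole.groupby("acq_year")["mean_ms"].mean()
        jump = yearly[2] - yearly[1]
        assert jump == pytest.approx((1.1 - 1.0) * base + 2.0, abs=1e-9)

    def test_covariates_reproducible(self):
        cfg = CohortConfig(n_participants=5, timepoints=3, seed=8)
        assert draw_covariates(cfg).equals(draw_covariates(cfg))
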