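"""Percentage-change trajectories and the mixed-effects trajectory model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiprelax import (
    EmptyDataError,
    InputError,
    build_long_table,
    compare_null_full,
    fit_lme,
    percentage_change,
    positive_trend_fraction,
    simulate_lme_table,
)
from hiprelax.longitudinal import validate_long_table


class TestPercentageChange:
    @pytest.mark.parametrize(
        "initial,followup,expected", [(30.0, 33.0, 10.0), (40.0, 36.0, -10.0), (25.0, 25.0, 0.0)]
    )
    def test_examples(self, initial, followup, expected):
        assert percentage_change(initial, followup) == pytest.approx(expected)

    def test_nonpositive_initial_errors(self):
        with pytest.raises(InputError):
            percentage_change(0.0, 10.0)
        with pytest.raises(InputError):
            percentage_change(-5.0, 10.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(1.0, 100.0), b=st.floats(1.0, 100.0))
    def test_exchange_identity(self, a, b):
        # pc(a, b) = -pc(b, a) * (b / a)
        assert percentage_change(a, b) == pytest.approx(-percentage_change(b, a) * (b / a))


def trend_table(changes, initial=30.0):
    rows = []
    for i, delta in enumerate(changes):
        for year, val in ((3, initial), (4, initial * (1 + delta / 100.0))):
            rows.append(
                dict(
                    participant_id=f"P{i:02d}", hip_side="L", acq_year=year, age=50.0,
                    sex="F", bmi=25.0, kl_score=1, cartilage="femur", region="WHOLE",
                    contrast="t1rho", mean_ms=val,
                )
            )
    return pd.DataFrame(rows)


class TestPositiveTrend:
    def test_13_of_25(self):
        changes = [5.0] * 13 + [-5.0] * 12
        assert positive_trend_fraction(trend_table(changes), "t1rho", "femur") == pytest.approx(52.0)

    def test_all_negative(self):
        assert positive_trend_fraction(trend_table([-1.0] * 10), "t1rho", "femur") == 0.0

    def test_missing_followup_excluded_from_denominator(self):
        tab = trend_table([5.0, 5.0, -5.0, -5.0])
        tab = tab[~((tab.participant_id == "P03") & (tab.acq_year == 4))]
        assert positive_trend_fraction(tab, "t1rho", "femur") == pytest.approx(100.0 * 2 / 3)

    def test_empty_denominator_errors(self):
        tab = trend_table([5.0])
        with pytest.raises(EmptyDataError):
            positive_trend_fraction(tab[tab.acq_year == 3], "t1rho", "femur")

    def test_yearly_drift_cohort(self):
        # +0.8 ms/year drift against 0.5 ms measurement noise over 4 years:
        # nearly every hip shows a positive baseline-to-final change
        table, _ = simulate_lme_table(
            coefficients={"bmi": 1.2, "acq_year": 0.8}, random_intercept_sd=2.0, residual_sd=0.5, seed=21
        )
        frac = positive_trend_fraction(table, "t1rho", "femur", initial_year=0, followup_year=4)
        assert frac > 90.0


class TestFitLme:
    def test_recovers_generating_coefficients(self):
        table, truth = simulate_lme_table(seed=3)
        res = fit_lme(table, "femur", "WHOLE", "t1rho")
        assert res.coef("bmi")["estimate"] == pytest.approx(1.2, abs=0.25)
        assert res.coef("acq_year")["estimate"] == pytest.approx(0.9, abs=0.2)
        assert res.converged and not res.singular
        assert res.n_obs == 180 and res.n_participants == 18

    def test_df_split_between_within(self):
        table, _ = simulate_lme_table(seed=3)
        res = fit_lme(table, "femur", "WHOLE", "t1rho")
        # acq_year and bmi vary within participants: n - groups - 2 = 180 - 18 - 2
        assert res.coef("acq_year")["df"] == 160.0
        # sex, age, kl are participant constants: groups - 3
        assert res.coef("sex_female")["df"] == 15.0

    def test_single_participant_errors(self):
        table, _ = simulate_lme_table(n_participants=1, seed=0)
        with pytest.raises(InputError):
            fit_lme(table, "femur", "WHOLE", "t1rho")

    def test_rank_deficient_design_errors(self):
        table, _ = simulate_lme_table(seed=4)
        table["kl_score"] = 0  # an all-zero column in an intercept-free design
        with pytest.raises(InputError, match="collinear|rank"):
            fit_lme(table, "femur", "WHOLE", "t1rho")

    def test_null_vs_full_lr_nonnegative(self):
        table, _ = simulate_lme_table(seed=5)
        out = compare_null_full(table, "femur", "WHOLE", "t1rho")
        assert out["lr_stat"] >= 0.0
        assert 0.0 <= out["p_value"] <= 1.0
        # under a strong BMI effect the covariates clearly beat the null model
        assert out["p_value"] < 0.01


class TestBuildLongTable:
    def _inputs(self, n_participants=3, timepoints=5):
        table, _ = simulate_lme_table(n_participants=n_participants, timepoints=timepoints, seed=6)
        region_means = table[
            ["participant_id", "hip_side", "acq_year", "cartilage", "region", "contrast", "mean_ms"]
        ].copy()
        covs = table[
            ["participant_id", "acq_year", "age", "sex", "bmi", "kl_score"]
        ].drop_duplicates(["participant_id", "acq_year"])
        return region_means, covs

    def test_cardinality(self):
        region_means, covs = self._inputs()
        out, report = build_long_table(region_means, covs)
        assert len(out) == 3 * 2 * 5  # participants x hips x years
        assert report["n_dropped_missing_covariates"] == 0

    def test_missing_bmi_rows_excluded_and_counted(self):
        region_means, covs = self._inputs()
        covs = covs.copy()
        covs.loc[covs.index[0], "bmi"] = np.nan
        out, report = build_long_table(region_means, covs)
        assert report["n_dropped_missing_covariates"] == 2  # both hips of that visit
        assert len(out) == 3 * 2 * 5 - 2

    def test_kl_filter(self):
        region_means, covs = self._inputs()
        covs = covs.copy()
        high = covs["participant_id"] == "P00"
        covs.loc[high, "kl_score"] = 4
        out, report = build_long_table(region_means, covs)
        assert report["n_dropped_kl"] == 10
        assert "P00" not in set(out["participant_id"])

    def test_disjoint_ids_error(self):
        region_means, covs = self._inputs()
        covs = covs.copy()
        covs["participant_id"] = covs["participant_id"] + "_other"
        with pytest.raises(EmptyDataError):
            build_long_table(region_means, covs)

    def test_duplicate_keys_error(self):
        region_means, covs = self._inputs()
        dup = pd.concat([region_means, region_means.iloc[[0]]], ignore_index=True)
        with pytest.raises(InputError):
            build_long_table(dup, covs)

    def test_validate_rejects_high_kl(self):
        table, _ = simulate_lme_table(n_participants=2, seed=7)
        table.loc[table.index[0], "kl_score"] = 4
        with pytest.raises(InputError):
            validate_long_table(table)
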