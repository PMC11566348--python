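"""Longitudinal trajectory analysis of cartilage relaxation-time means.

Tidy per-hip-per-timepoint records of region means and covariates (the "long table")
feed two analyses:

* percentage change between a baseline and a follow-up year, and the fraction of hips
  with a positive trend;
* a linear mixed-effects model per outcome (cartilage region x contrast) with fixed
  effects acquisition-year + sex + age + KL-score + BMI, no global intercept, and a
  random intercept per participant, fitted by REML (maximum likelihood available for
  likelihood-ratio comparisons).

Sex is coded as an indicator (female = 1).  Reported p-values use a t reference with
a within/between degrees-of-freedom split in the style of classical nested-model
software: covariates that vary within participants get residual degrees of freedom
``n_obs - n_groups - n_within_terms``; covariates constant within every participant
get ``n_groups - n_between_terms``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .errors import EmptyDataError, InputError

__all__ = [
    "LONG_TABLE_COLUMNS",
    "LmeResult",
    "validate_long_table",
    "percentage_change",
    "positive_trend_fraction",
    "fit_lme",
    "compare_null_full",
    "build_long_table",
]

logger = logging.getLogger(__name__)

#: Required columns of a long table, in canonical order.
LONG_TABLE_COLUMNS = [
    "participant_id",
    "hip_side",
    "acq_year",
    "age",
    "sex",
    "bmi",
    "kl_score",
    "cartilage",
    "region",
    "contrast",
    "mean_ms",
]

_KEY = ["participant_id", "hip_side", "acq_year", "cartilage", "region", "contrast"]
_FIXED_TERMS = ["acq_year", "sex_female", "age", "kl_score", "bmi"]


def validate_long_table(table: pd.DataFrame, max_kl: int = 3) -> pd.DataFrame:
    """Check a long table's schema, key uniqueness and KL inclusion criterion."""
    missing = [c for c in LONG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"long table is missing columns: {missing}")
    if table.duplicated(subset=_KEY).any():
        raise InputError("long table has duplicate (participant, hip, year, cartilage, region, contrast) keys")
    if (table["kl_score"] > max_kl).any():
        raise InputError(f"long table contains KL-score > {max_kl} rows (advanced OA excluded)")
    return table


@dataclass
class LmeResult:
    """Coefficient table and variance components of one mixed-effects fit."""

    table: pd.DataFrame  # columns: term, estimate, std_error, df, t_value, p_value
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    converged: bool
    singular: bool
    method: str
    loglike: float

    def coef(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for one fixed effect."""
        row = self.coef(term)
        tcrit = stats.t.ppf(0.5 + level / 2.0, df=row["df"])
        return (row["estimate"] - tcrit * row["std_error"], row["estimate"] + tcrit * row["std_error"])


def percentage_change(initial: float, followup: float) -> float:
    """Percentage change ``100 * (followup - initial) / initial``; initial must be > 0."""
    if not initial > 0:
        raise InputError(f"initial value must be positive, got {initial}")
    return 100.0 * (followup - initial) / initial


def positive_trend_fraction(
    table: pd.DataFrame,
    contrast: str,
    cartilage: str,
    region: str = "WHOLE",
    initial_year: int = 3,
    followup_year: int = 4,
) -> float:
    """Percentage of hips whose region mean increased between two study years.

    A hip enters the denominator only if it has both the initial-year and the
    follow-up-year row for the requested outcome.
    """
    sel = table[
        (table["contrast"] == contrast)
        & (table["cartilage"] == cartilage)
        & (table["region"] == region)
    ]
    wide = sel.pivot_table(
        index=["participant_id", "hip_side"], columns="acq_year", values="mean_ms"
    )
    if initial_year not in wide.columns or followup_year not in wide.columns:
        raise EmptyDataError("no hips with both the initial and follow-up year present")
    both = wide[[initial_year, followup_year]].dropna()
    if both.empty:
        raise EmptyDataError("no hips with both the initial and follow-up year present")
    pc = both.apply(lambda r: percentage_change(r[initial_year], r[followup_year]), axis=1)
    return 100.0 * float((pc > 0).sum()) / len(pc)


def _design(table: pd.DataFrame) -> pd.DataFrame:
    x = pd.DataFrame(index=table.index)
    x["acq_year"] = table["acq_year"].astype(float)
    sex = table["sex"]
    if sex.dtype == object or str(sex.dtype) == "category":
        x["sex_female"] = (sex.astype(str).str.upper().str[0] == "F").astype(float)
    else:
        x["sex_female"] = sex.astype(float)
    x["age"] = table["age"].astype(float)
    x["kl_score"] = table["kl_score"].astype(float)
    x["bmi"] = table["bmi"].astype(float)
    return x


def _term_dfs(x: pd.DataFrame, groups: pd.Series) -> dict[str, float]:
    """Within/between degrees-of-freedom split per fixed-effect term."""
    n_obs = len(x)
    n_groups = groups.nunique()
    within = {}
    for term in x.columns:
        varies = x[term].groupby(groups.values).nunique().gt(1).any()
        within[term] = bool(varies)
    n_within = sum(within.values())
    n_between = len(x.columns) - n_within
    df_within = max(n_obs - n_groups - n_within, 1)
    df_between = max(n_groups - n_between, 1)
    return {t: float(df_within if w else df_between) for t, w in within.items()}


def _fit_mixedlm(model: "sm.MixedLM", reml: bool):
    """Fit with a gradient-based optimizer, falling back to derivative-free methods
    when the profiled score becomes numerically singular (small cohorts)."""
    try:
        return model.fit(reml=reml, method=["lbfgs", "cg"])
    except np.linalg.LinAlgError:
        return model.fit(reml=reml, method=["powell", "nm"])


def fit_lme(
    table: pd.DataFrame,
    cartilage: str,
    region: str,
    contrast: str,
    reml: bool = True,
) -> LmeResult:
    """Fit the trajectory mixed-effects model for one outcome.

    Fixed effects: acquisition year, sex (female=1), age, KL-score and BMI, with no
    global intercept; random intercept per participant; REML by default.  Rows with
    missing covariates or outcome are dropped (logged).  A singular or non-converged
    fit is returned with flags set rather than raised; fewer than two participants is
    an error, since no between-participant variance is identifiable.
    """
    sel = table[
        (table["cartilage"] == cartilage)
        & (table["region"] == region)
        & (table["contrast"] == contrast)
    ].copy()
    if sel.empty:
        raise EmptyDataError(f"no rows for outcome ({cartilage}, {region}, {contrast})")
    needed = ["mean_ms", "acq_year", "sex", "age", "kl_score", "bmi", "participant_id"]
    n_before = len(sel)
    sel = sel.dropna(subset=needed)
    if len(sel) < n_before:
        logger.info("dropped %d rows with missing outcome/covariates", n_before - len(sel))
    if sel["participant_id"].nunique() < 2:
        raise InputError("mixed-effects fit needs at least two participants")

    x = _design(sel)
    # Guard against a rank-deficient fixed-effects design before the optimizer sees it.
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise InputError(f"rank-deficient design; most collinear terms: {pair}")

    y = sel["mean_ms"].astype(float)
    groups = sel["participant_id"]
    model = sm.MixedLM(endog=y, exog=x, groups=groups)
    singular = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = _fit_mixedlm(model, reml)
    for w in caught:
        msg = str(w.message).lower()
        if "singular" in msg or "boundary" in msg:
            singular = True
        if "converge" in msg or "convergence" in msg:
            converged = False
    if not getattr(fit, "converged", True):
        converged = False

    dfs = _term_dfs(x, groups)
    rows = []
    for term in x.columns:
        est = float(fit.fe_params[term])
        se = float(fit.bse_fe[term])
        df_t = dfs[term]
        tval = est / se if se > 0 else np.nan
        pval = 2.0 * stats.t.sf(abs(tval), df=df_t) if np.isfinite(tval) else np.nan
        rows.append(dict(term=term, estimate=est, std_error=se, df=df_t, t_value=tval, p_value=pval))
    re_var = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    return LmeResult(
        table=pd.DataFrame(rows),
        random_intercept_var=re_var,
        residual_var=float(fit.scale),
        n_obs=len(sel),
        n_participants=int(groups.nunique()),
        converged=converged,
        singular=singular or re_var <= 1e-10,
        method="REML" if reml else "ML",
        loglike=float(fit.llf),
    )


def compare_null_full(table: pd.DataFrame, cartilage: str, region: str, contrast: str) -> dict:
    """Likelihood-ratio comparison of an intercept-only null model against the full
    covariate model, both with a participant random intercept.

    Both models are fitted by maximum likelihood in nested parameterizations (the full
    model adds the five covariates to the null model's intercept) so the statistic is
    nonnegative by construction.  Returns the LR statistic, its degrees of freedom and
    the chi-square p-value.
    """
    sel = table[
        (table["cartilage"] == cartilage)
        & (table["region"] == region)
        & (table["contrast"] == contrast)
    ].dropna(subset=["mean_ms", "acq_year", "sex", "age", "kl_score", "bmi"])
    if sel["participant_id"].nunique() < 2:
        raise InputError("model comparison needs at least two participants")
    y = sel["mean_ms"].astype(float)
    groups = sel["participant_id"]
    x_full = _design(sel)
    x_full.insert(0, "intercept", 1.0)
    x_null = x_full[["intercept"]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_null = _fit_mixedlm(sm.MixedLM(y, x_null, groups=groups), reml=False)
        fit_full = _fit_mixedlm(sm.MixedLM(y, x_full, groups=groups), reml=False)
    lr = max(2.0 * (fit_full.llf - fit_null.llf), 0.0)
    df = x_full.shape[1] - x_null.shape[1]
    return {"lr_stat": float(lr), "df": int(df), "p_value": float(stats.chi2.sf(lr, df))}


def build_long_table(region_means: pd.DataFrame, covariates: pd.DataFrame, max_kl: int = 3) -> tuple[pd.DataFrame, dict]:
    """Join per-hip-per-year region means with the subject covariate table.

    ``region_means`` needs columns (participant_id, hip_side, acq_year, cartilage,
    region, contrast, mean_ms); ``covariates`` needs (participant_id, acq_year, age,
    sex, bmi, kl_score) — or per-participant covariates without ``acq_year``, which
    are then treated as constant over the study.  Rows failing the KL inclusion
    criterion or with missing covariates are excluded and counted in the report.
    """
    rm_key = ["participant_id", "hip_side", "acq_year", "cartilage", "region", "contrast"]
    for c in rm_key + ["mean_ms"]:
        if c not in region_means.columns:
            raise InputError(f"region_means is missing column {c!r}")
    if region_means.duplicated(subset=rm_key).any():
        raise InputError("region_means has duplicate keys")
    cov_needed = ["participant_id", "age", "sex", "bmi", "kl_score"]
    for c in cov_needed:
        if c not in covariates.columns:
            raise InputError(f"covariates is missing column {c!r}")
    join_key = ["participant_id"] + (["acq_year"] if "acq_year" in covariates.columns else [])
    if covariates.duplicated(subset=join_key).any():
        raise InputError("covariates has duplicate keys")

    merged = region_means.merge(covariates, on=join_key, how="inner")
    report = {"n_region_rows": len(region_means), "n_joined": len(merged)}
    if merged.empty:
        raise EmptyDataError("join produced no rows (disjoint participant IDs?)")

    n0 = len(merged)
    merged = merged.dropna(subset=["age", "sex", "bmi", "kl_score", "mean_ms"])
    report["n_dropped_missing_covariates"] = n0 - len(merged)
    n1 = len(merged)
    merged = merged[merged["kl_score"] <= max_kl]
    report["n_dropped_kl"] = n1 - len(merged)
    if merged.empty:
        raise EmptyDataError("no rows survive covariate/KL filtering")

    merged = merged[LONG_TABLE_COLUMNS].reset_index(drop=True)
    return validate_long_table(merged, max_kl=max_kl), report
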