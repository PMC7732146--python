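"""Population statistics for cohort stiffness panels.

Implements the statistical layer of a community stiffness study: stratified
summaries by sex and age decade, Student t / one-way ANOVA group tests,
quintile assignment with logistic odds-ratio models (unadjusted "Model 1" and
age-adjusted "Model 2"), the Cochran–Armitage chi-square test for linear trend
across quintiles, blood-pressure-category contrasts versus the normal-BP
group, and ordinary-least-squares predictive models of each index on
(age, sex code, SBP, DBP, smoking-years, risk count).

Ordinary model fits are delegated to :mod:`statsmodels` and
:mod:`scipy.stats`; only the trend test is closed-form in-house.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import ConfigurationError, SingularFitError, ValidationError
from .reference_values import ENROLLMENT_EXCLUSION_PCT, MODEL_COVARIATES

__all__ = [
    "QuintileORRow",
    "RegressionModel",
    "GroupTestResult",
    "enrollment_analyzable_percent",
    "stratified_summary",
    "group_tests",
    "quintile_assign",
    "quintile_or",
    "trend_test",
    "percent_change",
    "bp_category_contrasts",
    "fit_predictive_models",
    "predict_index",
]

AGE_BANDS = ("30-39", "40-49", "50-59", ">=60")
INDEX_COLUMNS = ("beta", "ep", "ac", "pwv_beta")


@dataclass(frozen=True)
class QuintileORRow:
    """One quintile of one index with Model-1/Model-2 odds ratios."""

    index_name: str
    quintile: int  # 1..5
    lower: float
    upper: float
    n: int
    n_events: int
    or_unadj: float | None
    ci_low: float | None
    ci_high: float | None
    or_adj: float | None = None
    ci_low_adj: float | None = None
    ci_high_adj: float | None = None
    separated: bool = False


@dataclass(frozen=True)
class RegressionModel:
    """An OLS predictive model for one stiffness index."""

    index_name: str
    coefficients: dict[str, float]  # keyed by MODEL_COVARIATES
    intercept: float
    r_squared: float
    stderr: dict[str, float] = field(default_factory=dict)
    n: int = 0

    def linear_predictor(
        self,
        *,
        age: float,
        sex_code: int,
        sbp: float,
        dbp: float,
        smoking_years: float,
        n_cmr: int,
    ) -> float:
        c = self.coefficients
        return (
            c["age"] * age
            + c["sex_code"] * sex_code
            + c["sbp"] * sbp
            + c["dbp"] * dbp
            + c["smoking_years"] * smoking_years
            + c["n_cmr"] * n_cmr
            + self.intercept
        )


@dataclass(frozen=True)
class GroupTestResult:
    kind: str  # "t" or "anova"
    statistic: float
    df: tuple[float, ...]
    p_value: float


def enrollment_analyzable_percent(
    exclusion_percents: dict[str, float] | None = None,
) -> float:
    """Percent of enrolled subjects retained after the stated exclusions."""
    exc = ENROLLMENT_EXCLUSION_PCT if exclusion_percents is None else exclusion_percents
    total_excluded = float(sum(exc.values()))
    if not 0.0 <= total_excluded <= 100.0:
        raise ConfigurationError("exclusion percentages must total within [0, 100]")
    return 100.0 - total_excluded


def age_band(age: float) -> str:
    if age < 40:
        return AGE_BANDS[0]
    if age < 50:
        return AGE_BANDS[1]
    if age < 60:
        return AGE_BANDS[2]
    return AGE_BANDS[3]


def stratified_summary(
    cohort: pd.DataFrame,
    index_cols: tuple[str, ...] = INDEX_COLUMNS,
    *,
    exclude_htn_dm: bool = False,
) -> pd.DataFrame:
    """Per (sex × age-decade) stratum n, mean and SD of each index.

    ``cohort`` needs ``age``, ``sex`` and the index columns; with
    ``exclude_htn_dm`` it also needs the ``high_bp`` and ``elevated_fpg`` risk
    flags, and subjects satisfying either criterion (threshold or treatment)
    are dropped — the implementable reading of "excluding hypertensives and/or
    subjects with diabetes".  Empty strata appear with n = 0 and null stats.
    """
    df = cohort.copy()
    if exclude_htn_dm:
        df = df[~(df["high_bp"].astype(bool) | df["elevated_fpg"].astype(bool))]
    df["age_band"] = df["age"].map(age_band)
    rows = []
    for sex in ("male", "female"):
        for band in AGE_BANDS:
            sub = df[(df["sex"] == sex) & (df["age_band"] == band)]
            row: dict[str, object] = {"sex": sex, "age_band": band, "n": len(sub)}
            for col in index_cols:
                if len(sub) == 0:
                    row[f"{col}_mean"] = np.nan
                    row[f"{col}_sd"] = np.nan
                else:
                    row[f"{col}_mean"] = float(sub[col].mean())
                    row[f"{col}_sd"] = (
                        float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def group_tests(groups: list[np.ndarray]) -> GroupTestResult:
    """Student t (pooled variance) for two groups, one-way ANOVA for more."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValidationError("need >= 2 groups with n >= 2 each")
    if len(groups) == 2:
        t, p = scipy.stats.ttest_ind(groups[0], groups[1], equal_var=True)
        df = groups[0].size + groups[1].size - 2
        return GroupTestResult("t", float(t), (float(df),), float(p))
    f, p = scipy.stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return GroupTestResult("anova", float(f), (float(k - 1), float(n - k)), float(p))


def quintile_assign(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quintile labels (1..5) and interior boundaries for a sample.

    Boundaries are the 20/40/60/80 empirical percentiles under the
    linear-interpolation quantile definition; a value equal to a boundary is
    assigned to the lower quintile.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5 or np.unique(values).size < 5:
        raise ValidationError("need >= 5 distinct values for quintiles")
    boundaries = np.percentile(values, [20, 40, 60, 80])
    labels = 1 + (values[:, None] > boundaries[None, :]).sum(axis=1)
    return labels.astype(int), boundaries


def _wald_or(params, cov, idx) -> tuple[float, float, float]:
    coef = float(params[idx])
    se = float(np.sqrt(cov[idx, idx]))
    return float(np.exp(coef)), float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))


def quintile_or(
    outcome: np.ndarray,
    quintiles: np.ndarray,
    age: np.ndarray | None = None,
    *,
    index_name: str = "",
    values: np.ndarray | None = None,
) -> list[QuintileORRow]:
    """Logistic odds ratios of a binary outcome across ordered quintiles.

    Model 1 regresses the outcome on quintile indicators (first quintile is
    the reference, OR ≡ 1); Model 2 (fitted when ``age`` is given) adds
    continuous age in years.  Confidence intervals are 95% Wald.  A quintile
    whose outcome is constant (complete separation) is returned flagged with
    null CIs.  With two levels the Model-1 OR equals the 2×2 cross-product
    ratio.
    """
    outcome = np.asarray(outcome).astype(int)
    quintiles = np.asarray(quintiles).astype(int)
    levels = np.unique(quintiles)
    if set(np.unique(outcome)) - {0, 1}:
        raise ValidationError("outcome must be binary 0/1")
    ref = levels[0]
    separated = {
        int(q): len(np.unique(outcome[quintiles == q])) < 2 for q in levels
    }
    usable = ~np.isin(quintiles, [q for q, s in separated.items() if s and q != ref])

    def fit(with_age: bool):
        mask = usable
        lv = [q for q in levels if q == ref or not separated[int(q)]]
        x_cols = [(quintiles[mask] == q).astype(float) for q in lv if q != ref]
        X = np.column_stack(x_cols) if x_cols else np.empty((mask.sum(), 0))
        if with_age:
            X = np.column_stack([X, np.asarray(age, dtype=float)[mask]])
        X = sm.add_constant(X, has_constant="add")
        res = sm.Logit(outcome[mask], X).fit(disp=0, maxiter=200)
        out = {}
        for j, q in enumerate([q for q in lv if q != ref]):
            out[int(q)] = _wald_or(res.params, res.cov_params(), j + 1)
        return out

    ors1 = fit(False)
    ors2 = fit(True) if age is not None else {}

    rows = []
    for q in levels:
        qi = int(q)
        in_q = quintiles == q
        if values is not None:
            lower, upper = float(np.min(values[in_q])), float(np.max(values[in_q]))
        else:
            lower = upper = float("nan")
        base = dict(
            index_name=index_name,
            quintile=qi,
            lower=lower,
            upper=upper,
            n=int(in_q.sum()),
            n_events=int(outcome[in_q].sum()),
        )
        if q == ref:
            rows.append(
                QuintileORRow(
                    **base, or_unadj=1.0, ci_low=1.0, ci_high=1.0,
                    or_adj=1.0 if age is not None else None,
                    ci_low_adj=1.0 if age is not None else None,
                    ci_high_adj=1.0 if age is not None else None,
                )
            )
        elif separated[qi]:
            rows.append(
                QuintileORRow(
                    **base, or_unadj=None, ci_low=None, ci_high=None, separated=True
                )
            )
        else:
            o1 = ors1[qi]
            o2 = ors2.get(qi)
            rows.append(
                QuintileORRow(
                    **base,
                    or_unadj=o1[0], ci_low=o1[1], ci_high=o1[2],
                    or_adj=o2[0] if o2 else None,
                    ci_low_adj=o2[1] if o2 else None,
                    ci_high_adj=o2[2] if o2 else None,
                )
            )
    return rows


def trend_test(counts: np.ndarray, scores: np.ndarray | None = None) -> GroupTestResult:
    """Cochran–Armitage chi-square test for linear trend in a 2×k table.

    ``counts`` has rows (events, non-events) and one column per ordered
    category; ``scores`` default to 1..k.  Returns the 1-df chi-square
    statistic and its p-value.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValidationError("counts must be a 2 x k table")
    n_i = counts.sum(axis=0)
    if np.any(n_i == 0) or counts.sum(axis=1).min() == 0:
        raise ValidationError("zero-margin row or column in trend table")
    k = counts.shape[1]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    N = counts.sum()
    r_i = counts[0]
    p_bar = r_i.sum() / N
    num = float((s * (r_i - n_i * p_bar)).sum()) ** 2
    den = p_bar * (1 - p_bar) * float((n_i * s**2).sum() - (n_i * s).sum() ** 2 / N)
    if den == 0.0:
        raise ValidationError("degenerate trend table")
    chi2 = num / den
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return GroupTestResult("trend", float(chi2), (1.0,), p)


def percent_change(baseline: float, delta: float, *, decimals: int = 1) -> float:
    """100·Δ/baseline, rounded to the reporting precision (one decimal)."""
    if baseline == 0.0:
        raise ValidationError("baseline mean of zero")
    return round(100.0 * delta / baseline, decimals)


def bp_category_contrasts(
    cohort: pd.DataFrame,
    index_cols: tuple[str, ...] = INDEX_COLUMNS,
    *,
    category_col: str = "bp_category",
) -> pd.DataFrame:
    """Per-BP-category mean, Δ versus the normal group, and percent change.

    Requires a non-empty normal category.  Percent changes are rounded to one
    decimal, the precision used in reports.
    """
    if (cohort[category_col] == "normal").sum() == 0:
        raise ValidationError("empty normal-BP reference group")
    rows = []
    base = {c: float(cohort.loc[cohort[category_col] == "normal", c].mean()) for c in index_cols}
    for cat in ("normal", "elevated", "stage1", "stage2", "crisis"):
        sub = cohort[cohort[category_col] == cat]
        row: dict[str, object] = {"bp_category": cat, "n": len(sub)}
        for c in index_cols:
            if len(sub) == 0:
                row[f"{c}_mean"] = np.nan
                row[f"{c}_delta"] = np.nan
                row[f"{c}_pct"] = np.nan
                continue
            m = float(sub[c].mean())
            row[f"{c}_mean"] = m
            row[f"{c}_delta"] = m - base[c]
            row[f"{c}_pct"] = percent_change(base[c], m - base[c])
        rows.append(row)
    return pd.DataFrame(rows)


def fit_predictive_models(
    cohort: pd.DataFrame,
    index_cols: tuple[str, ...] = INDEX_COLUMNS,
) -> dict[str, RegressionModel]:
    """OLS of each index on (age, sex code, SBP, DBP, smoking-years, n_cmr).

    ``cohort`` must provide the covariates under the names in
    :data:`carostiff.reference_values.MODEL_COVARIATES`.  Raises
    :class:`SingularFitError` on a (numerically) collinear design.
    """
    if len(cohort) <= 50:
        raise ValidationError("need n > 50 subjects for the predictive models")
    X = cohort.loc[:, list(MODEL_COVARIATES)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0.0):
        raise SingularFitError("zero-variance covariate in design matrix")
    Xc = sm.add_constant(X, has_constant="add")
    cond = float(np.linalg.cond(Xc))
    if cond > 1e10:
        raise SingularFitError(f"collinear design (condition number {cond:.2e})")
    models = {}
    for name in index_cols:
        y = cohort[name].to_numpy(dtype=float)
        res = sm.OLS(y, Xc).fit()
        coeffs = {k: float(res.params[j + 1]) for j, k in enumerate(MODEL_COVARIATES)}
        stderr = {k: float(res.bse[j + 1]) for j, k in enumerate(MODEL_COVARIATES)}
        models[name] = RegressionModel(
            index_name=name,
            coefficients=coeffs,
            intercept=float(res.params[0]),
            r_squared=float(res.rsquared),
            stderr=stderr,
            n=len(cohort),
        )
    return models


def predict_index(
    model: RegressionModel,
    *,
    age: float,
    sex_code: int,
    sbp: float,
    dbp: float,
    smoking_years: float,
    n_cmr: int,
) -> float:
    """Evaluate a predictive model's linear predictor exactly."""
    if sex_code not in (1, 2):
        raise ValidationError("sex_code must be 1 (male) or 2 (female)")
    if not 0 <= n_cmr <= 5:
        raise ValidationError("n_cmr must be in 0..5")
    if age < 0 or smoking_years < 0 or sbp <= 0 or dbp <= 0:
        raise ValidationError("covariates out of range")
    return model.linear_predictor(
        age=age, sex_code=sex_code, sbp=sbp, dbp=dbp,
        smoking_years=smoking_years, n_cmr=n_cmr,
    )
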