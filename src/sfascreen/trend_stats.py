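"""Cohort age-trend analytics: trendlines, slope interactions, convergence.

Within-cohort age trends are ordinary least squares of an outcome on age
(age is centred at the pooled mean before fitting for numerical stability;
reported intercepts are on the age-0 scale).  Slope differences between
cohorts are estimated from an age-by-group interaction model on the
two-cohort subset, mirroring the estimate +/- SD (CI), p presentation of
group-comparison tables.  Convergence of two trendlines is the closed-form
intersection age.  Cohort comparisons use Kruskal-Wallis for continuous
variables and the chi-square test on contingency tables for categorical
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_io import COHORTS, Dataset
from .exceptions import FitError, ValidationError

__all__ = [
    "TrendFit",
    "SlopeComparison",
    "fit_trend",
    "compare_slopes",
    "convergence_age",
    "group_comparison",
    "OUTCOME_ALIASES",
]

#: Derived outcome names resolvable against dataset columns.
OUTCOME_ALIASES: dict[str, str] = {"GM_TIV": "vol_cerebral_cortex"}


@dataclass(frozen=True)
class TrendFit:
    """A within-cohort linear age trend.

    ``intercept`` is on the age-0 scale so two fits intersect at
    ``(intercept_b - intercept_a) / (slope_a - slope_b)``.
    """

    cohort: str
    outcome: str
    slope: float
    intercept: float
    slope_se: float
    ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class SlopeComparison:
    """Age-by-group interaction: slope(cmp) - slope(ref), with SE, CI, p."""

    ref_cohort: str
    cmp_cohort: str
    outcome: str
    estimate: float
    sd: float
    ci: tuple[float, float]
    p: float


def _outcome_column(data: Dataset, outcome: str) -> str:
    col = OUTCOME_ALIASES.get(outcome, outcome)
    if col not in data.frame.columns:
        raise ValidationError(f"outcome {outcome!r} not found in dataset")
    return col


def fit_trend(data: Dataset, cohort: str, outcome: str) -> TrendFit:
    """OLS of ``outcome`` on age within one cohort.

    Slope standard error comes from standard linear-model theory; with
    only two points the fit is perfect and the undefined SE is flagged as
    NaN with a warning.
    """
    col = _outcome_column(data, outcome)
    sub = data.cohort_frame(cohort)
    sub = sub[sub[col].notna() & sub["age"].notna()]
    if len(sub) < 3 and len(sub) != 2:
        raise FitError(f"need >= 3 records for a trend, got {len(sub)}")
    age = sub["age"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise FitError("constant age: trend is singular")
    centre = age.mean()
    X = sm.add_constant(age - centre)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    intercept0 = float(fit.params[0]) - slope * centre
    if len(sub) == 2:
        warnings.warn("two-point trend: perfect fit, slope SE undefined", stacklevel=2)
        se = float("nan")
    else:
        se = float(fit.bse[1])
    return TrendFit(
        cohort=cohort,
        outcome=outcome,
        slope=slope,
        intercept=intercept0,
        slope_se=se,
        ci95=(slope - 1.96 * se, slope + 1.96 * se),
        n=len(sub),
    )


def compare_slopes(
    data: Dataset, ref_cohort: str, cmp_cohort: str, outcome: str
) -> SlopeComparison:
    """Age-by-group slope interaction between two cohorts.

    Fits ``outcome ~ age + group + age x group`` on the two-cohort subset
    with ``ref_cohort`` as the reference level and returns the interaction
    coefficient (the slope difference), its standard error, 95% CI and
    two-sided p.  By the interaction coding this estimate equals
    ``fit_trend(cmp).slope - fit_trend(ref).slope`` exactly.
    """
    col = _outcome_column(data, outcome)
    frames = {}
    for cohort in (ref_cohort, cmp_cohort):
        sub = data.cohort_frame(cohort)
        sub = sub[sub[col].notna() & sub["age"].notna()]
        if len(sub) < 3:
            raise FitError(f"need >= 3 records in {cohort}, got {len(sub)}")
        frames[cohort] = sub
    both = pd.concat(frames.values(), ignore_index=True)
    age = both["age"].to_numpy(dtype=float)
    centre = age.mean()
    age_c = age - centre
    is_cmp = (both["cohort"] == cmp_cohort).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age_c), age_c, is_cmp, age_c * is_cmp])
    y = both[col].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("singular interaction design")
    fit = sm.OLS(y, X).fit()
    est = float(fit.params[3])
    se = float(fit.bse[3])
    lo, hi = fit.conf_int()[3]
    return SlopeComparison(
        ref_cohort=ref_cohort,
        cmp_cohort=cmp_cohort,
        outcome=outcome,
        estimate=est,
        sd=se,
        ci=(float(lo), float(hi)),
        p=float(fit.pvalues[3]),
    )


def convergence_age(fit_a: TrendFit, fit_b: TrendFit, tol: float = 1e-9) -> float | None:
    """Age at which two trendlines intersect; None for (near-)parallel lines.

    Symmetric in its arguments.
    """
    if fit_a.outcome != fit_b.outcome:
        raise ValidationError(
            f"fits describe different outcomes: {fit_a.outcome!r} vs {fit_b.outcome!r}"
        )
    dslope = fit_a.slope - fit_b.slope
    if abs(dslope) <= tol:
        return None
    return (fit_b.intercept - fit_a.intercept) / dslope


def group_comparison(data: Dataset, variable: str, kind: str = "continuous"):
    """Three-cohort comparison of one variable.

    Continuous variables: Kruskal-Wallis H across the three cohorts.
    Categorical variables: chi-square on the cohort x category table.
    Returns ``(statistic, p)``.
    """
    if kind not in ("continuous", "categorical"):
        raise ValidationError(f"kind must be continuous|categorical, got {kind!r}")
    col = _outcome_column(data, variable)
    groups = []
    for cohort in COHORTS:
        vals = data.cohort_frame(cohort)[col].dropna()
        if vals.empty:
            raise FitError(f"cohort {cohort} has no observations of {variable}")
        groups.append(vals)
    if kind == "continuous":
        stat, p = stats.kruskal(*[g.to_numpy(dtype=float) for g in groups])
        return float(stat), float(p)
    table = pd.crosstab(data.frame["cohort"], data.frame[col])
    stat, p, _, _ = stats.chi2_contingency(table)
    return float(stat), float(p)
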