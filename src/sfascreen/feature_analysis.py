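"""Feature-importance rankings and region-score correlation tables.

The predictive potential of each structural measure is ranked by
impurity-based importance, averaged over four tree ensembles (random
forest, extra trees, AdaBoost, gradient boosting) fitted on one cohort's
(features -> score) problem.  Region-score association is quantified by
Pearson correlation between each Desikan-Killiany cortical volume and the
test score within a cohort, with a significance flag at a configurable
level (uncorrected by default, Benjamini-Hochberg optionally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from statsmodels.stats.multitest import multipletests

from .data_io import Dataset
from .exceptions import FitError, RankingError
from .features import cortical_volume_columns, feature_set_columns

__all__ = [
    "FeatureRanking",
    "RegionCorrelation",
    "rank_features",
    "correlate_regions",
    "DEFAULT_ENSEMBLES",
]

#: Ensemble name -> (estimator class, fixed hyperparameters).  Tree counts
#: are deliberately generous for stable impurity estimates.
DEFAULT_ENSEMBLES: dict[str, tuple[type, dict]] = {
    "random_forest": (RandomForestRegressor, {"n_estimators": 500, "n_jobs": 1}),
    "extra_trees": (ExtraTreesRegressor, {"n_estimators": 500, "n_jobs": 1}),
    "adaboost": (AdaBoostRegressor, {"n_estimators": 100}),
    "gradient_boosting": (GradientBoostingRegressor, {"n_estimators": 300}),
}


@dataclass(frozen=True)
class FeatureRanking:
    """Aggregated impurity-importance ranking for one (cohort, test).

    ``entries`` has one row per feature, sorted by descending mean
    importance, with per-ensemble importance columns; within every
    ensemble (and for the aggregate) the importances sum to 1.
    """

    cohort: str
    test: str
    entries: pd.DataFrame
    ensembles_used: tuple[str, ...]

    def top(self, k: int) -> list[str]:
        return list(self.entries.index[:k])


@dataclass(frozen=True)
class RegionCorrelation:
    region: str
    r: float
    p: float
    significant: bool


def rank_features(
    data: Dataset,
    cohort: str,
    test: str,
    seed: int = 0,
    feature_set: str = "VBM+SBM",
    ensembles: dict | None = None,
) -> FeatureRanking:
    """Rank structural predictors of one cohort's test score.

    Fits the four tree ensembles on (features -> score), normalises each
    ensemble's impurity importances to sum to 1, and aggregates them by
    their arithmetic mean.  Columns are canonicalised (sorted by name)
    before fitting so the ranking does not depend on input column order.
    Deterministic given ``seed``.
    """
    ensembles = ensembles if ensembles is not None else DEFAULT_ENSEMBLES
    cols = sorted(feature_set_columns(data.feature_names, feature_set))
    if not cols:
        raise FitError(f"no {feature_set} features in dataset")
    sub = data.cohort_frame(cohort)
    usable = sub[sub[test].notna() & sub[cols].notna().all(axis=1)]
    if len(usable) < 20:
        warnings.warn(
            f"only {len(usable)} usable records for ({cohort}, {test}); "
            "importance estimates will be unstable",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise FitError(f"need >= 2 usable records, got {len(usable)}")
    y = usable[test].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise RankingError(f"{test} is constant in {cohort}: ranking undefined")
    X = usable[cols].to_numpy(dtype=float)

    per_ensemble = {}
    ss = np.random.SeedSequence(seed)
    for (name, (cls, params)), child in zip(sorted(ensembles.items()), ss.spawn(len(ensembles))):
        est = cls(random_state=int(child.generate_state(1)[0] % (2**31)), **params)
        est.fit(X, y)
        imp = np.asarray(est.feature_importances_, dtype=float)
        total = imp.sum()
        per_ensemble[name] = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    entries = pd.DataFrame(per_ensemble, index=cols)
    entries.insert(0, "importance", entries.mean(axis=1))
    entries["importance"] /= entries["importance"].sum()
    # descending importance, ties broken by name for bit-reproducible output
    entries = entries.loc[
        sorted(entries.index, key=lambda f: (-entries.loc[f, "importance"], f))
    ]
    entries.index.name = "feature"
    return FeatureRanking(
        cohort=cohort, test=test, entries=entries, ensembles_used=tuple(sorted(ensembles))
    )


def correlate_regions(
    data: Dataset,
    cohort: str,
    test: str,
    alpha_level: float = 0.05,
    regions: list[str] | None = None,
    correction: str = "none",
) -> list[RegionCorrelation]:
    """Pearson r between each cortical volume and the score, within a cohort.

    Zero-variance regions get ``r = nan`` and are flagged non-significant.
    ``correction="bh"`` applies Benjamini-Hochberg across regions before
    flagging.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"correction must be 'none' or 'bh', got {correction!r}")
    cols = regions if regions is not None else cortical_volume_columns(data.feature_names)
    sub = data.cohort_frame(cohort)
    out: list[tuple[str, float, float]] = []
    for col in cols:
        paired = sub[[col, test]].dropna()
        if len(paired) < 3:
            raise FitError(f"need >= 3 paired observations for {col}, got {len(paired)}")
        x = paired[col].to_numpy(dtype=float)
        y = paired[test].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"{col}: zero variance, correlation undefined", stacklevel=2)
            out.append((col, float("nan"), float("nan")))
            continue
        r, p = stats.pearsonr(x, y)
        out.append((col, float(r), float(p)))
    pvals = np.array([p for _, _, p in out])
    finite = np.isfinite(pvals)
    signif = np.zeros(len(out), dtype=bool)
    if correction == "bh" and finite.any():
        signif[finite] = multipletests(pvals[finite], alpha=alpha_level, method="fdr_bh")[0]
    else:
        signif[finite] = pvals[finite] < alpha_level
    return [
        RegionCorrelation(region=name, r=r, p=p, significant=bool(s))
        for (name, r, p), s in zip(out, signif)
    ]
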