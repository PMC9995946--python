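"""Cohort-specific ridge models linking morphometry to test scores.

Each model — an SFA "stamp" — is a ridge regression (L2 penalty
``alpha = 0.5`` by default, intercept unpenalised) fitted on one (cohort,
test, feature-set) triple, with features z-scored inside the training
sample.  Evaluation follows a subject-grouped repeated k-fold protocol and
reports the mean absolute error, its standard error, a 95% CI and the MAE
as a percentage of the test's empirical score range, which makes errors
comparable across scales of very different size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .data_io import COHORTS, Dataset
from .exceptions import DomainError, EvaluationError, FitError, PredictionError
from .features import feature_set_columns
from .scales import SCALES

__all__ = [
    "CohortSFAModel",
    "ModelEvaluation",
    "CVSpec",
    "fit_sfa_model",
    "predict_score",
    "predict_dataset",
    "evaluate_model_cv",
    "empirical_range",
    "mae_to_range_pct",
]

DEFAULT_ALPHA = 0.5


@dataclass(frozen=True)
class CohortSFAModel:
    """A fitted SFA stamp: ridge coefficients on standardized features."""

    cohort: str
    test: str
    feature_set: str
    alpha: float
    coefficients: pd.Series  # indexed by feature name, standardized scale
    intercept: float
    feature_means: pd.Series
    feature_sds: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.index)


@dataclass(frozen=True)
class ModelEvaluation:
    """Resampled MAE summary for one model configuration.

    ``mae_se`` is the standard error of the per-fold MAEs; ``ci95`` is
    ``mae_mean +/- 1.96 * mae_se`` and ``mae_range_pct`` is
    ``100 * mae_mean / range_used``.
    """

    cohort: str
    test: str
    feature_set: str
    mae_mean: float
    mae_se: float
    ci95: tuple[float, float]
    mae_range_pct: float
    n_splits: int
    range_used: float
    fold_maes: tuple[float, ...] = ()


@dataclass(frozen=True)
class CVSpec:
    k_folds: int = 10
    n_repeats: int = 10
    seed: int = 0


def _training_matrix(
    data: Dataset, cohort: str, test: str, feature_set: str
) -> tuple[pd.DataFrame, pd.Series]:
    if cohort not in COHORTS:
        raise FitError(f"unknown cohort {cohort!r}")
    cols = feature_set_columns(data.feature_names, feature_set)
    if not cols:
        raise FitError(f"dataset has no {feature_set} features")
    sub = data.cohort_frame(cohort)
    usable = sub[test].notna() & sub[cols].notna().all(axis=1)
    sub = sub[usable]
    return sub[cols], sub[test].astype(float)


def fit_sfa_model(
    train: Dataset,
    cohort: str,
    test: str,
    feature_set: str = "VBM",
    alpha: float = DEFAULT_ALPHA,
) -> CohortSFAModel:
    """Fit one (cohort, test, feature-set) ridge model.

    Features are z-scored on the training records; zero-variance features
    are dropped with a warning.  The coefficients minimise
    ``||y - Xw - b||^2 + alpha * ||w||^2`` with the intercept unpenalised,
    so predicting the training-mean feature vector returns the intercept.
    """
    if alpha <= 0:
        raise DomainError(f"ridge penalty alpha must be > 0, got {alpha}")
    X, y = _training_matrix(train, cohort, test, feature_set)
    if len(y) < 2:
        raise FitError(
            f"need >= 2 usable {cohort} records with {test} scores, got {len(y)}"
        )
    means = X.mean()
    sds = X.std(ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = list(sds.index[~keep])
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            stacklevel=2,
        )
    X = X.loc[:, keep]
    means, sds = means[keep], sds[keep]
    Z = (X - means) / sds
    model = Ridge(alpha=alpha, fit_intercept=True)
    model.fit(Z.to_numpy(), y.to_numpy())
    return CohortSFAModel(
        cohort=cohort,
        test=test,
        feature_set=feature_set,
        alpha=alpha,
        coefficients=pd.Series(model.coef_, index=X.columns),
        intercept=float(model.intercept_),
        feature_means=means,
        feature_sds=sds,
    )


def predict_score(model: CohortSFAModel, features: Mapping[str, float] | pd.Series) -> float:
    """Predict one subject's score from their feature vector.

    Returns ``intercept + coefficients . standardized(features)``; the
    prediction is deliberately NOT clipped to the scale bounds, preserving
    the raw residual geometry the classifier relies on.
    """
    if not isinstance(features, pd.Series):
        features = pd.Series(dict(features))
    missing = [f for f in model.feature_names if f not in features.index or pd.isna(features[f])]
    if missing:
        raise PredictionError(f"missing feature(s) for prediction: {missing[:5]}")
    z = (features[model.feature_names] - model.feature_means) / model.feature_sds
    return float(model.intercept + z @ model.coefficients)


def predict_dataset(model: CohortSFAModel, data: Dataset) -> pd.Series:
    """Vectorised predictions for every row of ``data`` (NaN rows propagate)."""
    X = data.frame[model.feature_names]
    Z = (X - model.feature_means) / model.feature_sds
    return Z @ model.coefficients + model.intercept


def _grouped_folds(subjects: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(subjects)
    return [fold for fold in np.array_split(order, k) if len(fold)]


def evaluate_model_cv(
    data: Dataset,
    cohort: str,
    test: str,
    feature_set: str = "VBM",
    alpha: float = DEFAULT_ALPHA,
    cv: CVSpec = CVSpec(),
) -> ModelEvaluation:
    """Subject-grouped repeated k-fold MAE for one model configuration.

    All visits of one subject stay in the same fold.  The reported spread
    is the standard error of the per-fold MAEs over ``k_folds * n_repeats``
    folds, and the normalised error divides by the pooled empirical range
    of the test.
    """
    cols = feature_set_columns(data.feature_names, feature_set)
    sub = data.cohort_frame(cohort)
    usable = sub[sub[test].notna() & sub[cols].notna().all(axis=1)]
    subjects = usable["subject_id"].unique()
    if len(subjects) < cv.k_folds:
        raise EvaluationError(
            f"{len(subjects)} subjects with usable {test} in {cohort}: "
            f"fewer than k={cv.k_folds} folds"
        )
    rng = np.random.default_rng(cv.seed)
    fold_maes: list[float] = []
    for _ in range(cv.n_repeats):
        for fold_subjects in _grouped_folds(subjects, cv.k_folds, rng):
            held = usable["subject_id"].isin(fold_subjects)
            train_frame = usable[~held]
            test_frame = usable[held]
            if train_frame.empty or test_frame.empty:
                continue
            train_ds = Dataset(
                frame=train_frame.reset_index(drop=True),
                feature_names=data.feature_names,
                provenance=data.provenance,
            )
            model = fit_sfa_model(train_ds, cohort, test, feature_set, alpha)
            X = test_frame[model.feature_names]
            Z = (X - model.feature_means) / model.feature_sds
            pred = Z.to_numpy() @ model.coefficients.to_numpy() + model.intercept
            fold_maes.append(float(np.mean(np.abs(pred - test_frame[test].to_numpy()))))
    if not fold_maes:
        raise EvaluationError("no usable folds")
    maes = np.asarray(fold_maes)
    mae_mean = float(maes.mean())
    mae_se = float(maes.std(ddof=1) / np.sqrt(len(maes))) if len(maes) > 1 else 0.0
    rng_used = empirical_range(data, test)
    return ModelEvaluation(
        cohort=cohort,
        test=test,
        feature_set=feature_set,
        mae_mean=mae_mean,
        mae_se=mae_se,
        ci95=(mae_mean - 1.96 * mae_se, mae_mean + 1.96 * mae_se),
        mae_range_pct=mae_to_range_pct(mae_mean, rng_used) if rng_used > 0 else float("nan"),
        n_splits=len(maes),
        range_used=rng_used,
        fold_maes=tuple(maes),
    )


def empirical_range(data: Dataset, test: str) -> float:
    """Max minus min observed score over the pooled (all-cohort) dataset."""
    if test not in SCALES:
        raise DomainError(f"unknown test {test!r}")
    vals = data.frame[test].dropna()
    if vals.empty:
        raise DomainError(f"no observed {test} scores")
    if len(vals) < 2:
        raise DomainError(f"need >= 2 observed {test} scores, got {len(vals)}")
    r = float(vals.max() - vals.min())
    if r == 0:
        warnings.warn(f"{test}: single distinct value; MAE/range is undefined", stacklevel=2)
    return r


def mae_to_range_pct(mae: float, score_range: float) -> float:
    """Mean absolute error as a percentage of the score range."""
    if score_range <= 0:
        raise DomainError(f"score range must be > 0, got {score_range}")
    return 100.0 * mae / score_range
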