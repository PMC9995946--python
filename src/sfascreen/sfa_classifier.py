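"""Screening by best-fitting SFA pattern with majority voting.

For every test, the three cohort models each predict the subject's score;
the absolute difference between prediction and the actual score is the
model's residual, and the smallest residual casts that test's vote.  The
final label is the modal vote over the test battery.  Tie handling is
deterministic and documented: per-test residual ties go to the less
severe label (CN over MCI over Dementia), and a three-way vote split is
resolved by the smallest range-normalised residual among the three
winning votes.  Performance is summarised as a 3x3 confusion matrix with
per-class true-positive rates in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import COHORTS, Dataset, SubjectRecord
from .exceptions import (
    ClassificationError,
    LeakageError,
    ValidationError,
    VoteError,
)
from .sfa_regression import (
    DEFAULT_ALPHA,
    CohortSFAModel,
    empirical_range,
    fit_sfa_model,
    predict_dataset,
    predict_score,
)

__all__ = [
    "ModelBank",
    "PerTestVote",
    "VoteResult",
    "ConfusionMatrix",
    "DEFAULT_VOTE_TESTS",
    "build_model_bank",
    "residuals_for_test",
    "vote_for_test",
    "classify_subject",
    "classify_dataset",
    "evaluate_classifier",
    "cross_validated_confusion",
]

#: Default voting battery: the tests whose cohort trendlines stay parallel,
#: where majority voting was found to help the most.
DEFAULT_VOTE_TESTS: tuple[str, ...] = ("MMSE", "ADAS13", "RAVLT_imm")


@dataclass
class ModelBank:
    """All cohort models for a feature set, plus the test battery and ranges."""

    models: dict[tuple[str, str], CohortSFAModel]  # (cohort, test) -> model
    tests: tuple[str, ...]
    feature_set: str
    training_subjects: set[str] = field(default_factory=set)
    ranges: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for test in self.tests:
            missing = [c for c in COHORTS if (c, test) not in self.models]
            if missing:
                raise ValidationError(f"bank incomplete for {test}: missing cohorts {missing}")

    def model(self, cohort: str, test: str) -> CohortSFAModel:
        return self.models[(cohort, test)]


@dataclass(frozen=True)
class PerTestVote:
    residuals: dict[str, float]  # cohort -> |prediction - actual|, score units
    normalized: dict[str, float]  # residuals in units of the test's range
    vote: str
    tie_broken: bool


@dataclass(frozen=True)
class VoteResult:
    subject_id: str
    per_test: dict[str, PerTestVote]
    final_label: str
    tie_broken: bool


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts (rows = true cohort, columns = assigned) plus class TPRs."""

    counts: pd.DataFrame
    tpr_per_class: dict[str, float]  # percent

    @classmethod
    def from_labels(cls, true_labels, assigned_labels) -> "ConfusionMatrix":
        counts = pd.DataFrame(0, index=list(COHORTS), columns=list(COHORTS), dtype=int)
        for t, a in zip(true_labels, assigned_labels):
            counts.loc[t, a] += 1
        tpr = {}
        for cohort in COHORTS:
            row_sum = int(counts.loc[cohort].sum())
            tpr[cohort] = 100.0 * counts.loc[cohort, cohort] / row_sum if row_sum else float("nan")
        return cls(counts=counts, tpr_per_class=tpr)


def build_model_bank(
    train: Dataset,
    tests=DEFAULT_VOTE_TESTS,
    feature_set: str = "VBM",
    alpha: float = DEFAULT_ALPHA,
) -> ModelBank:
    """Fit all (cohort, test) ridge models on the training data.

    Also records the training subjects (for leakage checks) and the
    empirical ranges used to normalise residuals across tests.
    """
    tests = tuple(tests)
    models = {
        (cohort, test): fit_sfa_model(train, cohort, test, feature_set, alpha)
        for test in tests
        for cohort in COHORTS
    }
    ranges = {t: empirical_range(train, t) for t in tests}
    return ModelBank(
        models=models,
        tests=tests,
        feature_set=feature_set,
        training_subjects=train.subject_ids,
        ranges=ranges,
    )


def residuals_for_test(bank: ModelBank, subject: SubjectRecord, test: str):
    """Per-cohort absolute residuals of one subject on one test.

    Returns ``(residuals, normalized)`` dicts keyed by cohort, or ``None``
    as the skip signal when the subject lacks this test's score (a missing
    score is not an error; a missing feature is).
    """
    if test not in bank.tests:
        raise ValidationError(f"bank has no models for test {test!r}")
    actual = subject.scores.get(test)
    if actual is None or not np.isfinite(actual):
        return None
    rng = bank.ranges.get(test, float("nan"))
    residuals, normalized = {}, {}
    for cohort in COHORTS:
        pred = predict_score(bank.model(cohort, test), subject.features)
        residuals[cohort] = abs(pred - actual)
        normalized[cohort] = residuals[cohort] / rng if rng and rng > 0 else float("nan")
    return residuals, normalized


def vote_for_test(residuals: dict[str, float]) -> tuple[str, bool]:
    """Argmin cohort of one test's residuals; ties prefer the less severe label."""
    finite = {c: r for c, r in residuals.items() if np.isfinite(r)}
    if not finite:
        raise VoteError("all residuals non-finite")
    best = min(finite.values())
    winners = [c for c in COHORTS if finite.get(c) == best]
    return winners[0], len(winners) > 1


def classify_subject(bank: ModelBank, subject: SubjectRecord, tests=None) -> VoteResult:
    """Assign a subject to the cohort whose SFA models fit them best.

    Per-test votes go to the minimal-residual cohort; the final label is
    the modal vote.  A three-way split is broken by the smallest
    range-normalised residual among the three winning votes.
    """
    tests = tuple(tests) if tests is not None else bank.tests
    per_test: dict[str, PerTestVote] = {}
    for test in tests:
        res = residuals_for_test(bank, subject, test)
        if res is None:
            continue
        residuals, normalized = res
        vote, tie = vote_for_test(residuals)
        per_test[test] = PerTestVote(
            residuals=residuals, normalized=normalized, vote=vote, tie_broken=tie
        )
    if not per_test:
        raise ClassificationError(f"subject {subject.subject_id}: no usable test")
    votes = pd.Series([v.vote for v in per_test.values()])
    tally = votes.value_counts()
    top = tally.max()
    leaders = [c for c in COHORTS if tally.get(c, 0) == top]
    tie_broken = len(leaders) > 1
    if not tie_broken:
        final = leaders[0]
    else:
        # split vote: smallest normalised residual among the winning votes
        best_score = np.inf
        final = leaders[0]
        for test, v in per_test.items():
            if v.vote in leaders and v.normalized[v.vote] < best_score:
                best_score = v.normalized[v.vote]
                final = v.vote
    return VoteResult(
        subject_id=subject.subject_id,
        per_test=per_test,
        final_label=final,
        tie_broken=tie_broken,
    )


def _vectorised_votes(bank: ModelBank, data: Dataset, tests) -> pd.DataFrame:
    """Per-test votes and winning normalised residuals for every row.

    Matrix form of :func:`classify_subject`; the scalar path is the
    reference implementation and the two are tested for agreement.
    """
    n = len(data)
    out = {}
    for test in tests:
        actual = data.frame[test].to_numpy(dtype=float)
        res = np.full((n, len(COHORTS)), np.nan)
        for j, cohort in enumerate(COHORTS):
            pred = predict_dataset(bank.model(cohort, test), data).to_numpy(dtype=float)
            res[:, j] = np.abs(pred - actual)
        usable = np.isfinite(actual)
        vote = np.full(n, -1)
        # argmin with ties resolved toward the less severe cohort: COHORTS
        # order means the first minimal index wins
        vote[usable] = np.argmin(res[usable], axis=1)
        rng = bank.ranges.get(test, float("nan"))
        win_norm = np.full(n, np.nan)
        win_norm[usable] = res[usable, vote[usable]] / rng if rng and rng > 0 else np.nan
        out[f"vote_{test}"] = vote
        out[f"norm_{test}"] = win_norm
    return pd.DataFrame(out, index=data.frame.index)


def classify_dataset(bank: ModelBank, data: Dataset, tests=None) -> pd.Series:
    """Final majority-vote labels for every usable row of ``data``."""
    tests = tuple(tests) if tests is not None else bank.tests
    votes = _vectorised_votes(bank, data, tests)
    vote_cols = [f"vote_{t}" for t in tests]
    norm_cols = [f"norm_{t}" for t in tests]
    labels = []
    vmat = votes[vote_cols].to_numpy()
    nmat = votes[norm_cols].to_numpy()
    for i in range(len(votes)):
        row = vmat[i]
        cast = row[row >= 0]
        if cast.size == 0:
            labels.append(None)
            continue
        counts = np.bincount(cast, minlength=len(COHORTS))
        top = counts.max()
        leaders = np.flatnonzero(counts == top)
        if len(leaders) == 1:
            labels.append(COHORTS[leaders[0]])
        else:
            best, final = np.inf, COHORTS[leaders[0]]
            for j, v in enumerate(row):
                if v in leaders and np.isfinite(nmat[i, j]) and nmat[i, j] < best:
                    best = nmat[i, j]
                    final = COHORTS[v]
            labels.append(final)
    return pd.Series(labels, index=data.frame.index, name="assigned")


def evaluate_classifier(
    bank: ModelBank, eval_data: Dataset, tests=None, allow_overlap: bool = False
) -> ConfusionMatrix:
    """Confusion matrix and per-class TPR of the bank on held-out data.

    Training and evaluation subjects must be disjoint; overlap raises
    :class:`LeakageError` unless explicitly (and loudly) overridden.
    """
    overlap = bank.training_subjects & eval_data.subject_ids
    if overlap:
        if not allow_overlap:
            raise LeakageError(
                f"{len(overlap)} subject(s) appear in both training and evaluation data"
            )
        warnings.warn(
            f"evaluating on {len(overlap)} training subject(s): results are optimistic",
            stacklevel=2,
        )
    assigned = classify_dataset(bank, eval_data, tests)
    usable = assigned.notna()
    return ConfusionMatrix.from_labels(
        eval_data.frame.loc[usable, "cohort"], assigned[usable]
    )


def cross_validated_confusion(
    data: Dataset,
    tests=DEFAULT_VOTE_TESTS,
    feature_set: str = "VBM",
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> ConfusionMatrix:
    """Subject-grouped k-fold cross-validated confusion matrix.

    Banks are refitted with each fold's subjects held out and the held-out
    assignments pooled into a single matrix.
    """
    subjects = data.frame["subject_id"].unique()
    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    true_all, assigned_all = [], []
    for fold in np.array_split(order, n_folds):
        held = data.frame["subject_id"].isin(fold).to_numpy()
        bank = build_model_bank(data.select_rows(~held), tests, feature_set, alpha)
        eval_ds = data.select_rows(held)
        assigned = classify_dataset(bank, eval_ds, tests)
        usable = assigned.notna()
        true_all.extend(eval_ds.frame.loc[usable, "cohort"])
        assigned_all.extend(assigned[usable])
    return ConfusionMatrix.from_labels(true_all, assigned_all)
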