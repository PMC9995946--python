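"""Ridge SFA models: closed-form oracle, CV protocol, MAE/range identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfascreen import (
    CVSpec,
    default_config,
    empirical_range,
    evaluate_model_cv,
    fit_sfa_model,
    generate_cohorts,
    mae_to_range_pct,
    noise_free_config,
    predict_score,
)
from sfascreen.exceptions import DomainError, EvaluationError, FitError, PredictionError

from conftest import make_dataset


def _tiny_regression_frame(rng, n=12, p=3, cohort="CN", noise=0.0, weights=None):
    w = weights if weights is not None else rng.normal(size=p)
    X = rng.normal(size=(n, p))
    y = 20.0 + X @ w + noise * rng.normal(size=n)
    frame = pd.DataFrame(X, columns=[f"vol_f{j}" for j in range(p)])
    frame["subject_id"] = [f"s{i}" for i in range(n)]
    frame["age"] = 70.0
    frame["cohort"] = cohort
    frame["MMSE"] = np.clip(y, 0, 30)
    return frame, w


def closed_form_ridge(Z, y, alpha):
    """Penalised normal equations on centred data: the independent oracle."""
    Zc = Z - Z.mean(axis=0)
    yc = y - y.mean()
    w = np.linalg.solve(Zc.T @ Zc + alpha * np.eye(Z.shape[1]), Zc.T @ yc)
    b = y.mean() - w @ Z.mean(axis=0)
    return w, b


class TestFit:
    def test_noiseless_limit_recovers_slope(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"vol_x": rng.normal(size=30)})
        frame["MMSE"] = 15.0 + 2.5 * frame["vol_x"]
        frame["subject_id"] = [f"s{i}" for i in range(30)]
        frame["age"] = 70.0
        frame["cohort"] = "CN"
        model = fit_sfa_model(make_dataset(frame), "CN", "MMSE", "VBM", alpha=1e-12)
        # coefficient is on the standardized scale: slope * sd(x)
        sd = frame["vol_x"].std(ddof=0)
        assert model.coefficients["vol_x"] == pytest.approx(2.5 * sd, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 40), p=st.integers(1, 6))
    def test_matches_closed_form_oracle(self, seed, n, p):
        """Fitted coefficients equal (Z'Z + aI)^-1 Z'y on centred data."""
        rng = np.random.default_rng(seed)
        frame, _ = _tiny_regression_frame(rng, n=n, p=p, noise=1.0)
        ds = make_dataset(frame)
        model = fit_sfa_model(ds, "CN", "MMSE", "VBM", alpha=0.5)
        cols = model.feature_names
        Z = ((frame[cols] - model.feature_means) / model.feature_sds).to_numpy()
        w, b = closed_form_ridge(Z, frame["MMSE"].to_numpy(), 0.5)
        np.testing.assert_allclose(model.coefficients.to_numpy(), w, atol=1e-8)
        assert model.intercept == pytest.approx(b, abs=1e-8)

    def test_alpha_stored_and_validated(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(_tiny_regression_frame(rng)[0])
        assert fit_sfa_model(ds, "CN", "MMSE").alpha == 0.5
        with pytest.raises(DomainError):
            fit_sfa_model(ds, "CN", "MMSE", alpha=0.0)

    def test_too_few_records(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(_tiny_regression_frame(rng, n=1)[0])
        with pytest.raises(FitError):
            fit_sfa_model(ds, "CN", "MMSE")

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        frame, _ = _tiny_regression_frame(rng)
        frame["vol_const"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_sfa_model(make_dataset(frame), "CN", "MMSE")
        assert "vol_const" not in model.feature_names


class TestPredict:
    def test_mean_feature_vector_maps_to_intercept(self):
        rng = np.random.default_rng(4)
        frame, _ = _tiny_regression_frame(rng, noise=0.5)
        ds = make_dataset(frame)
        model = fit_sfa_model(ds, "CN", "MMSE")
        mean_vec = frame[model.feature_names].mean()
        assert predict_score(model, mean_vec) == pytest.approx(model.intercept, abs=1e-10)

    def test_beats_zero_coefficient_model_on_training_data(self):
        rng = np.random.default_rng(5)
        frame, _ = _tiny_regression_frame(rng, n=40, noise=0.5)
        ds = make_dataset(frame)
        model = fit_sfa_model(ds, "CN", "MMSE")
        preds = [predict_score(model, row[model.feature_names]) for _, row in frame.iterrows()]
        mae_model = np.mean(np.abs(np.array(preds) - frame["MMSE"]))
        mae_null = np.mean(np.abs(frame["MMSE"].mean() - frame["MMSE"]))
        assert mae_model <= mae_null + 1e-12

    def test_missing_feature_named_in_error(self):
        rng = np.random.default_rng(6)
        ds = make_dataset(_tiny_regression_frame(rng)[0])
        model = fit_sfa_model(ds, "CN", "MMSE")
        with pytest.raises(PredictionError, match="vol_f0"):
            predict_score(model, {"vol_f1": 0.1, "vol_f2": 0.2})

    def test_generative_consistency_noise_free(self, small_config):
        """Own-cohort residuals vanish on noise-free synthetic subjects."""
        ds = generate_cohorts(noise_free_config(small_config), seed=17)
        model = fit_sfa_model(ds, "MCI", "ADAS13", "VBM+SBM", alpha=1e-8)
        sub = ds.frame[ds.frame["cohort"] == "MCI"].head(10)
        for _, row in sub.iterrows():
            pred = predict_score(model, row[model.feature_names])
            assert abs(pred - row["ADAS13"]) < 1e-6


class TestEvaluateCV:
    def test_fold_mean_matches_hand_oracle(self):
        """mae_mean is exactly the average of explicitly recomputed fold MAEs."""
        rng = np.random.default_rng(7)
        frame, _ = _tiny_regression_frame(rng, n=16, noise=1.0)
        ds = make_dataset(frame)
        cv = CVSpec(k_folds=4, n_repeats=2, seed=11)
        ev = evaluate_model_cv(ds, "CN", "MMSE", cv=cv)
        # oracle: replay the documented split protocol by hand
        subjects = frame["subject_id"].unique()
        fold_rng = np.random.default_rng(11)
        maes = []
        for _ in range(2):
            order = fold_rng.permutation(subjects)
            for fold in np.array_split(order, 4):
                held = frame["subject_id"].isin(fold)
                train = make_dataset(frame[~held].reset_index(drop=True))
                model = fit_sfa_model(train, "CN", "MMSE")
                Z = (frame.loc[held, model.feature_names] - model.feature_means) / model.feature_sds
                pred = Z.to_numpy() @ model.coefficients.to_numpy() + model.intercept
                maes.append(np.mean(np.abs(pred - frame.loc[held, "MMSE"].to_numpy())))
        assert ev.mae_mean == pytest.approx(np.mean(maes), abs=1e-12)
        assert ev.n_splits == 8

    def test_evaluation_invariants_hold(self, small_dataset):
        ev = evaluate_model_cv(
            small_dataset, "CN", "MMSE", "VBM", cv=CVSpec(k_folds=5, n_repeats=2, seed=1)
        )
        lo, hi = ev.ci95
        assert lo == pytest.approx(ev.mae_mean - 1.96 * ev.mae_se)
        assert hi == pytest.approx(ev.mae_mean + 1.96 * ev.mae_se)
        assert ev.mae_range_pct == pytest.approx(100 * ev.mae_mean / ev.range_used)
        assert ev.mae_mean >= 0 and ev.mae_se >= 0

    def test_zero_noise_near_perfect(self, small_config):
        ds = generate_cohorts(noise_free_config(small_config), seed=19)
        ev = evaluate_model_cv(ds, "CN", "DSST", "VBM", cv=CVSpec(k_folds=5, n_repeats=1, seed=2))
        assert ev.mae_mean < 0.05 * ds.frame.loc[ds.frame.cohort == "CN", "DSST"].std()

    def test_constant_outcome_gives_zero_mae(self):
        rng = np.random.default_rng(8)
        frame, _ = _tiny_regression_frame(rng, n=20, noise=1.0)
        frame["MMSE"] = 25.0
        ev = evaluate_model_cv(
            make_dataset(frame), "CN", "MMSE", cv=CVSpec(k_folds=4, n_repeats=1, seed=0)
        )
        assert ev.mae_mean == pytest.approx(0.0, abs=1e-10)

    def test_fewer_subjects_than_folds(self):
        rng = np.random.default_rng(9)
        ds = make_dataset(_tiny_regression_frame(rng, n=4)[0])
        with pytest.raises(EvaluationError):
            evaluate_model_cv(ds, "CN", "MMSE", cv=CVSpec(k_folds=10))

    def test_mae_nondecreasing_in_score_noise(self):
        """More score noise can only hurt held-out MAE (averaged over seeds)."""
        import dataclasses

        n = {"CN": 120, "MCI": 0, "Dementia": 0}
        levels = [0.0, 0.5, 1.0, 2.0]
        mean_maes = []
        for scale in levels:
            maes = []
            for seed in range(20):
                cfg = dataclasses.replace(
                    default_config(n_per_cohort=n, seed=100 + seed), score_noise_scale=scale
                )
                ds = generate_cohorts(cfg)
                ev = evaluate_model_cv(
                    ds, "CN", "MMSE", "VBM", cv=CVSpec(k_folds=5, n_repeats=1, seed=seed)
                )
                maes.append(ev.mae_mean)
            mean_maes.append(np.mean(maes))
        assert all(a <= b + 1e-9 for a, b in zip(mean_maes, mean_maes[1:]))

    def test_cohort_error_ordering_mirrors_severity(self, small_dataset):
        """MMSE MAE/range rises from CN through MCI to dementia, as the
        cohort score spreads do."""
        pct = {
            c: evaluate_model_cv(
                small_dataset, c, "MMSE", "VBM", cv=CVSpec(k_folds=5, n_repeats=2, seed=3)
            ).mae_range_pct
            for c in ("CN", "MCI", "Dementia")
        }
        assert pct["CN"] < pct["MCI"] < pct["Dementia"]


class TestRangeNormalisation:
    def test_empirical_range_is_max_minus_min(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "age": [70.0, 71.0, 72.0],
                "cohort": ["CN", "MCI", "Dementia"],
                "MMSE": [24.0, 30.0, 18.0],
                "vol_x": [0.1, 0.2, 0.3],
            }
        )
        assert empirical_range(make_dataset(frame), "MMSE") == 12.0

    def test_degenerate_single_value_warns(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "age": [70.0, 71.0],
                "cohort": ["CN", "CN"],
                "MMSE": [24.0, 24.0],
                "vol_x": [0.1, 0.2],
            }
        )
        with pytest.warns(UserWarning, match="undefined"):
            assert empirical_range(make_dataset(frame), "MMSE") == 0.0

    def test_mae_to_range_pct(self):
        assert mae_to_range_pct(0.0, 18.0) == 0.0
        assert mae_to_range_pct(0.81, 18.0) == pytest.approx(4.5)
        with pytest.raises(DomainError):
            mae_to_range_pct(1.0, 0.0)
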