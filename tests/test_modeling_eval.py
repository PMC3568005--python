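"""Metrics against independent oracles; cross-validation and holdout behavior."""

import json
import warnings

import numpy as np
import pytest

from mixqspr import (
    EstimatorSpec,
    SyntheticSpec,
    balanced_accuracy,
    crossvalidate,
    evaluate_holdout,
    generate_mixture_dataset,
    make_plan,
    overlap_report,
    q2,
    r2_pearson,
    recall_per_class,
    rmse,
)
from mixqspr.errors import ConfigError, LeakageError, UndefinedMetricError
from mixqspr.mixture_data import MixtureDataset
from mixqspr.validation_splits import FoldPlan

from conftest import opaque_dataset


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert r2_pearson(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert q2(y, y) == pytest.approx(1.0)

    def test_r2_affine_invariance(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert r2_pearson(y, 3.0 * y - 7.0) == pytest.approx(1.0)

    def test_r2_hand_computed_case(self):
        y_true = np.array([0.0, 1.0, 2.0, 3.0])
        y_pred = np.array([0.0, 1.0, 2.0, 0.0])
        # Pearson r of these vectors, squared, computed independently
        expected = float(np.corrcoef(y_true, y_pred)[0, 1]) ** 2
        assert r2_pearson(y_true, y_pred) == pytest.approx(expected, abs=1e-12)

    def test_rmse_hand_computed_case(self):
        assert rmse([0.0, 0.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0]) == 1.0

    def test_q2_of_mean_predictor_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert q2(y, np.full(4, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_undefined_cases_raise(self):
        with pytest.raises(UndefinedMetricError):
            r2_pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedMetricError):
            r2_pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(UndefinedMetricError):
            q2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_against_independent_implementations(self, rng):
        """1000 random cases agree with sklearn / direct-formula oracles to 1e-10."""
        from scipy.stats import pearsonr
        from sklearn.metrics import mean_squared_error, r2_score

        for _ in range(1000):
            n = int(rng.integers(3, 30))
            yt = rng.normal(size=n)
            yp = yt + rng.normal(scale=0.5, size=n)
            assert r2_pearson(yt, yp) == pytest.approx(
                pearsonr(yt, yp).statistic ** 2, abs=1e-10
            )
            assert rmse(yt, yp) == pytest.approx(
                float(np.sqrt(mean_squared_error(yt, yp))), abs=1e-10
            )
            assert q2(yt, yp) == pytest.approx(float(r2_score(yt, yp)), abs=1e-10)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert balanced_accuracy(y, y) == 1.0
        assert recall_per_class(y, y) == {0.0: 1.0, 1.0: 1.0}

    def test_majority_predictor_on_balanced_set(self):
        y = np.array([0.0] * 5 + [1.0] * 5)
        pred = np.zeros(10)
        assert recall_per_class(y, pred) == {0.0: 1.0, 1.0: 0.0}
        assert balanced_accuracy(y, pred) == 0.5

    def test_confusion_matrix_case(self):
        # 7/10 zeotropes and 9/10 azeotropes recalled -> 0.8
        y_true = np.array([0.0] * 10 + [1.0] * 10)
        y_pred = np.concatenate([np.r_[np.zeros(7), np.ones(3)],
                                 np.r_[np.ones(9), np.zeros(1)]])
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.8)

    def test_single_class_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            balanced_accuracy(np.zeros(4), np.zeros(4))

    def test_against_sklearn(self, rng):
        from sklearn.metrics import balanced_accuracy_score, recall_score

        for _ in range(200):
            n = int(rng.integers(4, 50))
            yt = rng.integers(0, 2, size=n).astype(float)
            if len(np.unique(yt)) < 2:
                continue
            yp = rng.integers(0, 2, size=n).astype(float)
            assert balanced_accuracy(yt, yp) == pytest.approx(
                float(balanced_accuracy_score(yt, yp)), abs=1e-10
            )
            rec = recall_per_class(yt, yp)
            assert rec[1.0] == pytest.approx(
                float(recall_score(yt, yp, pos_label=1)), abs=1e-10
            )


def linear_study(seed=0, gamma=0.0, sigma_c=0.0, noise=0.01):
    spec = SyntheticSpec(
        n_compounds=40,
        m_descriptors=6,
        n_pairs=100,
        compositions_per_mixture=5,
        interaction_strength=gamma,
        compound_effect_sd=sigma_c,
        noise_sd=noise,
        endpoint="bubble_like",
        seed=seed,
    )
    return generate_mixture_dataset(spec)


class TestCrossvalidate:
    def test_linear_estimator_recovers_additive_data(self):
        """A perfectly additive study is nearly exactly fit by a linear model
        on mole-weighted features."""
        ds, matrix, _ = linear_study()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            plan = make_plan(ds, "points_out", 5, seed=0)
        report = crossvalidate(ds, matrix, "WEIGHTED_SUM", plan,
                               EstimatorSpec("regression", "linear"), seed=0)
        assert report.aggregate["r2"][0] >= 0.99
        assert report.pooled["q2"] >= 0.99

    def test_mean_predictor_gives_q2_near_zero(self):
        """Pooled Q2 of a training-mean predictor stays within sampling noise of 0."""
        ds, matrix, _ = linear_study(seed=1, noise=0.5)
        y = np.array([r.value for r in ds.records])
        q2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(y))
            folds = np.array_split(idx, 5)
            preds = np.empty_like(y)
            for f in folds:
                train_mask = np.ones(len(y), bool)
                train_mask[f] = False
                preds[f] = y[train_mask].mean()
            q2s.append(q2(y, preds))
        assert all(abs(v) < 0.1 for v in q2s)

    def test_reports_are_deterministic(self, small_regression_study):
        ds, matrix, _ = small_regression_study
        plan = make_plan(ds, "mixtures_out", 5, seed=2)
        est = EstimatorSpec("regression", "rf", {"n_estimators": 20})
        r1 = crossvalidate(ds, matrix, "WEIGHTED_SUM", plan, est, seed=2)
        r2_ = crossvalidate(ds, matrix, "WEIGHTED_SUM", plan, est, seed=2)
        assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(
            r2_.to_dict(), sort_keys=True
        )

    def test_estimator_kind_must_match_endpoint(self, small_regression_study):
        ds, matrix, _ = small_regression_study
        plan = make_plan(ds, "mixtures_out", 5, seed=0)
        with pytest.raises(ConfigError):
            crossvalidate(ds, matrix, "WEIGHTED_SUM", plan,
                          EstimatorSpec("classification", "rfc"), seed=0)

    def test_invalid_plan_is_a_hard_failure(self, small_regression_study):
        ds, matrix, _ = small_regression_study
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            points = make_plan(ds, "points_out", 5, seed=0)
        forged = FoldPlan("MIXTURES_OUT", 5, points.assignment, 0)
        with pytest.raises(LeakageError):
            crossvalidate(ds, matrix, "WEIGHTED_SUM", forged,
                          EstimatorSpec("regression", "ridge"), seed=0)

    def test_no_leakage_through_scaling(self, small_regression_study):
        """Replacing test-fold target values with noise leaves training-fold
        predictions unchanged: nothing from the test fold reaches the model."""
        ds, matrix, _ = small_regression_study
        plan = make_plan(ds, "mixtures_out", 5, seed=0)
        est = EstimatorSpec("regression", "ridge")
        base = crossvalidate(ds, matrix, "WEIGHTED_SUM", plan, est, seed=0)

        rng = np.random.default_rng(0)
        fold0 = set(plan.test_indices(0))
        from dataclasses import replace
        noisy_records = [
            replace(r, value=float(rng.normal())) if i in fold0 else r
            for i, r in enumerate(ds.records)
        ]
        noisy = MixtureDataset(noisy_records, ds.property, ds.endpoint_kind,
                               ds.concentration_dependent)
        perturbed = crossvalidate(noisy, matrix, "WEIGHTED_SUM", plan, est, seed=0)
        # fold 0's model trained without its own targets: predictions identical
        assert perturbed.per_fold[0]["predictions"] == base.per_fold[0]["predictions"]
        # but its metrics do change, since the fold's truth changed
        assert perturbed.per_fold[0]["metrics"] != base.per_fold[0]["metrics"]


class TestClassificationCrossvalidate:
    def test_azeotrope_pipeline_beats_chance(self):
        spec = SyntheticSpec(n_compounds=40, m_descriptors=6, n_pairs=150,
                             endpoint="azeotrope_label", interaction_strength=1.0,
                             seed=5)
        ds, matrix, _ = generate_mixture_dataset(spec)
        plan = make_plan(ds, "mixtures_out", 5, seed=5)
        report = crossvalidate(ds, matrix, "SUM_ABSDIFF", plan,
                               EstimatorSpec("classification", "rfc"), seed=5)
        assert report.pooled["balanced_accuracy"] > 0.6
        assert set(report.aggregate) >= {"balanced_accuracy", "recall_0.0", "recall_1.0"}


class TestHoldout:
    def test_overlap_classification(self):
        train = opaque_dataset([("A", "B", 0.7), ("A", "C", 0.8)])
        shared = opaque_dataset([("A", "B", 0.6)])
        assert overlap_report(train, shared).classification == "points-out-like"
        assert overlap_report(train, shared).shared_pairs == 1
        mixtures = opaque_dataset([("B", "C", 0.7)])
        assert overlap_report(train, mixtures).classification == "mixtures-out-like"
        compounds = opaque_dataset([("A", "Z", 0.7)])
        assert overlap_report(train, compounds).classification == "compounds-out-like"

    def test_compounds_out_holdout_is_harder(self):
        """Held-out mixtures of unseen compounds are predicted worse than
        held-out mixtures of seen compounds, on average over seeds."""
        deltas = []
        for seed in range(10):
            ds, matrix, _ = linear_study(seed=seed, gamma=1.0, sigma_c=1.0, noise=0.1)
            plan_m = make_plan(ds, "mixtures_out", 5, seed=seed)
            plan_c = make_plan(ds, "compounds_out", 5, seed=seed)
            est = EstimatorSpec("regression", "rf", {"n_estimators": 50})

            def split(plan):
                test = [ds.records[i] for i in plan.test_indices(0)]
                train = [ds.records[i] for i in plan.train_indices(0)]
                mk = lambda rs: MixtureDataset(rs, ds.property, "regression", True)
                return mk(train), mk(test)

            rm, _ = evaluate_holdout(*split(plan_m), matrix, "WEIGHTED_SUM", est, seed=seed)
            rc, _ = evaluate_holdout(*split(plan_c), matrix, "WEIGHTED_SUM", est, seed=seed)
            deltas.append(rc.pooled["rmse"] - rm.pooled["rmse"])
        assert np.mean(deltas) > 0

    def test_empty_test_set_rejected(self, small_regression_study):
        ds, matrix, _ = small_regression_study
        empty = MixtureDataset([], ds.property, "regression", True)
        with pytest.raises(ConfigError):
            evaluate_holdout(ds, empty, matrix, "WEIGHTED_SUM",
                             EstimatorSpec("regression", "ridge"))
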