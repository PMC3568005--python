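"""Model training, protocol-aware cross-validation, and evaluation metrics.

Metrics follow the conventions of mixture-QSPR reporting:

* R²   — squared Pearson correlation between observed and predicted values
  (affine-invariant; undefined when either side is constant);
* RMSE — root mean squared error;
* Q²   — cross-validated determination coefficient
  ``1 - PRESS / TSS`` on pooled out-of-fold predictions, with the mean taken
  from the same pooled truth;
* balanced accuracy — mean of the per-class recalls of a binary classifier.

Cross-validation results are reported per fold and aggregated as
mean ± standard deviation across folds; pooled statistics (Q², pooled R²)
are computed over all out-of-fold predictions together, since fold-averaged
and pooled conventions can differ noticeably.

Estimators are pluggable: anything with a seeded ``fit(X, y)`` /
``predict(X)`` contract works. Shipped stand-ins for the neural-network /
LibSVM / random-forest engines of the original studies are scikit-learn
models (ridge and plain linear regression, RBF support vectors, random
forests, k-nearest neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .component_descriptors import DescriptorMatrix, scale_columns
from .errors import ConfigError, LeakageError, UndefinedMetricError
from .mixture_data import MixtureDataset
from .mixture_descriptors import MixtureFeatureTable, featurize_dataset
from .validation_splits import FoldPlan, audit_plan

# ---------------------------------------------------------------------------
# Metrics


def r2_pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation coefficient.

    Raises :class:`UndefinedMetricError` when fewer than 3 points are given or
    either vector is constant (the correlation is then undefined and must be
    reported as missing, not as 0).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ConfigError("y_true and y_pred must have equal length")
    if y_true.size < 3:
        raise UndefinedMetricError(f"R^2 requires n >= 3, got {y_true.size}")
    st, sp = y_true.std(), y_pred.std()
    if st == 0 or sp == 0:
        raise UndefinedMetricError("R^2 undefined for constant inputs")
    r = float(np.mean((y_true - y_true.mean()) * (y_pred - y_pred.mean())) / (st * sp))
    return min(r * r, 1.0)


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ConfigError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise UndefinedMetricError("RMSE requires n >= 1")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def q2(y_true_cv: np.ndarray, y_pred_cv: np.ndarray) -> float:
    """Cross-validated determination coefficient 1 - PRESS/TSS.

    Intended for pooled out-of-fold predictions; the reference mean is the
    mean of the pooled truth. Can be negative (worse than predicting the
    mean). Undefined for zero-variance truth.
    """
    y_true_cv = np.asarray(y_true_cv, dtype=float)
    y_pred_cv = np.asarray(y_pred_cv, dtype=float)
    if y_true_cv.shape != y_pred_cv.shape:
        raise ConfigError("y_true and y_pred must have equal length")
    if y_true_cv.size < 3:
        raise UndefinedMetricError(f"Q^2 requires n >= 3, got {y_true_cv.size}")
    tss = float(np.sum((y_true_cv - y_true_cv.mean()) ** 2))
    if tss == 0:
        raise UndefinedMetricError("Q^2 undefined for zero-variance truth")
    press = float(np.sum((y_true_cv - y_pred_cv) ** 2))
    return 1.0 - press / tss


def recall_per_class(y_true: np.ndarray, y_pred: np.ndarray) -> dict[Any, float]:
    """Per-class recall: correct-in-class / class size, for each true class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ConfigError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise UndefinedMetricError("recall requires n >= 1")
    out: dict[Any, float] = {}
    for cls in np.unique(y_true):
        mask = y_true == cls
        out[cls.item() if hasattr(cls, "item") else cls] = float(
            np.mean(y_pred[mask] == cls)
        )
    return out


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of the two per-class recalls of a binary classifier."""
    recalls = recall_per_class(y_true, y_pred)
    if len(recalls) != 2:
        raise UndefinedMetricError(
            f"balanced accuracy requires both classes present, got {sorted(recalls)}"
        )
    return float(np.mean(list(recalls.values())))


# ---------------------------------------------------------------------------
# Estimators


@dataclass
class EstimatorSpec:
    """A pluggable learning method: kind ('regression'/'classification'),
    registry id, and hyperparameter overrides."""

    kind: str
    id: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)


def make_estimator(spec: EstimatorSpec, seed: int = 0):
    """Instantiate a seeded scikit-learn estimator from a spec."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "regression":
        if spec.id == "ridge":
            from sklearn.linear_model import Ridge

            return Ridge(alpha=hp.pop("alpha", 1.0), random_state=seed, **hp)
        if spec.id == "linear":
            from sklearn.linear_model import LinearRegression

            return LinearRegression(**hp)
        if spec.id == "svr":
            from sklearn.svm import SVR

            return SVR(kernel=hp.pop("kernel", "rbf"), **hp)
        if spec.id == "rf":
            from sklearn.ensemble import RandomForestRegressor

            return RandomForestRegressor(
                n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
            )
        if spec.id == "knn":
            from sklearn.neighbors import KNeighborsRegressor

            return KNeighborsRegressor(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    elif spec.kind == "classification":
        if spec.id == "svc":
            from sklearn.svm import SVC

            return SVC(kernel=hp.pop("kernel", "rbf"), random_state=seed, **hp)
        if spec.id == "rfc":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
            )
        if spec.id == "knnc":
            from sklearn.neighbors import KNeighborsClassifier

            return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    else:
        raise ConfigError(f"unknown estimator kind: {spec.kind!r}")
    raise ConfigError(f"unknown estimator id for {spec.kind}: {spec.id!r}")


# ---------------------------------------------------------------------------
# Reports


@dataclass
class EvaluationReport:
    """Per-fold and aggregated metrics for one model/scheme/protocol run."""

    protocol: str
    scheme: str
    estimator_id: str
    seed: int
    per_fold: list[dict]
    aggregate: dict[str, tuple[float, float]]
    pooled: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "scheme": self.scheme,
            "estimator": self.estimator_id,
            "seed": self.seed,
            "per_fold": self.per_fold,
            "aggregate": {m: {"mean": v[0], "sd": v[1]} for m, v in self.aggregate.items()},
            "pooled": self.pooled,
        }


def _aggregate(per_fold: list[dict]) -> dict[str, tuple[float, float]]:
    """Mean ± standard deviation of each metric over folds where it is defined."""
    keys = {k for fold in per_fold for k in fold["metrics"]}
    out: dict[str, tuple[float, float]] = {}
    for k in sorted(keys):
        vals = [f["metrics"][k] for f in per_fold if k in f["metrics"]]
        if vals:
            out[k] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def _fold_metrics(kind: str, y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    metrics: dict[str, float] = {}
    if kind == "regression":
        metrics["rmse"] = rmse(y_true, y_pred)
        try:
            metrics["r2"] = r2_pearson(y_true, y_pred)
        except UndefinedMetricError:
            pass  # reported missing for this fold
    else:
        try:
            metrics["balanced_accuracy"] = balanced_accuracy(y_true, y_pred)
        except UndefinedMetricError:
            pass
        for cls, rec in recall_per_class(y_true, y_pred).items():
            metrics[f"recall_{cls}"] = rec
    return metrics


# ---------------------------------------------------------------------------
# Cross-validation


def crossvalidate(
    dataset: MixtureDataset,
    matrix: DescriptorMatrix,
    scheme: str,
    plan: FoldPlan,
    estimator: EstimatorSpec,
    seed: int = 0,
    scaling: str = "zscore",
) -> EvaluationReport:
    """Protocol-aware external cross-validation.

    For each fold, the descriptor scaler is fitted on the compounds of the
    training records only, then the estimator is fitted on the training rows
    and evaluated on the fold — no test-fold information reaches scaling or
    fitting. Compounds-out training exclusions (purged records) are honored.
    Regression reports include fold-averaged R²/RMSE and pooled Q² and R² over
    all out-of-fold predictions.
    """
    if estimator.kind != dataset.endpoint_kind:
        raise ConfigError(
            f"estimator kind {estimator.kind!r} does not match endpoint "
            f"{dataset.endpoint_kind!r}"
        )
    fresh_audit = audit_plan(plan, dataset)
    if not fresh_audit.ok:
        raise LeakageError(
            f"fold plan fails its {plan.protocol} audit with "
            f"{fresh_audit.n_violations} violation(s)"
        )

    table = featurize_dataset(dataset, matrix, scheme)
    kind = dataset.endpoint_kind

    per_fold: list[dict] = []
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    for f in range(plan.k):
        train_idx = plan.train_indices(f)
        test_idx = plan.test_indices(f)
        if not train_idx or not test_idx:
            raise ConfigError(f"fold {f} has an empty training or test set")

        train_compounds = {
            c for i in train_idx for c in dataset.records[i].compounds()
        }
        scaled_matrix, _ = scale_columns(matrix, method=scaling, fit_on=train_compounds)
        fold_table = featurize_dataset(dataset, scaled_matrix, scheme)

        X, y = fold_table.X, fold_table.y
        model = make_estimator(estimator, seed=seed)
        model.fit(X[train_idx], y[train_idx])
        y_pred = np.asarray(model.predict(X[test_idx]))
        y_test = y[test_idx]

        per_fold.append(
            {
                "fold": f,
                "n_test": len(test_idx),
                "n_train": len(train_idx),
                "test_indices": list(test_idx),
                "predictions": [float(v) for v in y_pred],
                "metrics": _fold_metrics(kind, y_test, y_pred),
            }
        )
        pooled_true.append(y_test)
        pooled_pred.append(y_pred)

    pooled: dict[str, float] = {}
    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    if kind == "regression":
        pooled["q2"] = q2(yt, yp)
        pooled["rmse"] = rmse(yt, yp)
        try:
            pooled["r2"] = r2_pearson(yt, yp)
        except UndefinedMetricError:
            pass
    else:
        try:
            pooled["balanced_accuracy"] = balanced_accuracy(yt, yp)
        except UndefinedMetricError:
            pass
        for cls, rec in recall_per_class(yt, yp).items():
            pooled[f"recall_{cls}"] = rec

    return EvaluationReport(
        protocol=plan.protocol,
        scheme=scheme,
        estimator_id=estimator.id,
        seed=seed,
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        pooled=pooled,
    )


# ---------------------------------------------------------------------------
# Held-out evaluation


@dataclass
class OverlapReport:
    """Train/test relationship summary for a held-out evaluation."""

    shared_pairs: int
    shared_compounds: int
    n_test_pairs: int
    n_test_compounds: int
    classification: str  # points-out-like / mixtures-out-like / compounds-out-like

    def to_dict(self) -> dict:
        return {
            "shared_pairs": self.shared_pairs,
            "shared_compounds": self.shared_compounds,
            "n_test_pairs": self.n_test_pairs,
            "n_test_compounds": self.n_test_compounds,
            "classification": self.classification,
        }


def overlap_report(train: MixtureDataset, test: MixtureDataset) -> OverlapReport:
    """Classify a holdout relative to training by shared mixtures/compounds.

    Shared mixture pairs → points-out-like (weakest); no shared pairs but all
    test compounds known → mixtures-out-like; some test compounds entirely new
    → compounds-out-like.
    """
    train_pairs = {r.pair_key() for r in train.records if not r.is_pure}
    test_pairs = {r.pair_key() for r in test.records if not r.is_pure}
    train_compounds = set(train.compounds())
    test_compounds = set(test.compounds())
    shared_pairs = len(train_pairs & test_pairs)
    shared_compounds = len(train_compounds & test_compounds)
    if shared_pairs > 0:
        cls = "points-out-like"
    elif test_compounds <= train_compounds:
        cls = "mixtures-out-like"
    else:
        cls = "compounds-out-like"
    return OverlapReport(
        shared_pairs=shared_pairs,
        shared_compounds=shared_compounds,
        n_test_pairs=len(test_pairs),
        n_test_compounds=len(test_compounds),
        classification=cls,
    )


def evaluate_holdout(
    train_dataset: MixtureDataset,
    test_dataset: MixtureDataset,
    matrix: DescriptorMatrix,
    scheme: str,
    estimator: EstimatorSpec,
    seed: int = 0,
    scaling: str = "zscore",
) -> tuple[EvaluationReport, OverlapReport]:
    """Fit on the training set and evaluate on a held-out set.

    The returned overlap report states how hard the holdout is (shared
    mixtures or compounds between the two sets) so a strong test-set number
    is never quoted without its difficulty class.
    """
    if not test_dataset.records:
        raise ConfigError("empty test set")
    overlap = overlap_report(train_dataset, test_dataset)

    train_compounds = set(train_dataset.compounds())
    scaled_matrix, _ = scale_columns(matrix, method=scaling, fit_on=train_compounds)
    train_table = featurize_dataset(train_dataset, scaled_matrix, scheme)
    test_table = featurize_dataset(test_dataset, scaled_matrix, scheme)

    model = make_estimator(estimator, seed=seed)
    model.fit(train_table.X, train_table.y)
    y_pred = np.asarray(model.predict(test_table.X))
    y_test = test_table.y

    kind = train_dataset.endpoint_kind
    metrics = _fold_metrics(kind, y_test, y_pred)
    if kind == "regression":
        try:
            metrics["q2"] = q2(y_test, y_pred)
        except UndefinedMetricError:
            pass
    per_fold = [{"fold": 0, "n_test": len(y_test), "n_train": len(train_table.y),
                 "metrics": metrics}]
    report = EvaluationReport(
        protocol="HOLDOUT",
        scheme=scheme,
        estimator_id=estimator.id,
        seed=seed,
        per_fold=per_fold,
        aggregate=_aggregate(per_fold),
        pooled=dict(metrics),
    )
    return report, overlap


def consensus_predict(models: list, X: np.ndarray) -> np.ndarray:
    """Plain mean of several fitted regressors' predictions (optional)."""
    preds = np.vstack([np.asarray(m.predict(X), dtype=float) for m in models])
    return preds.mean(axis=0)
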