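"""Eleven-algorithm classification benchmark with support-weighted metrics.

Models are trained (optionally grid-searched by weighted F1 under
stratified cross-validation) on the SMOTE-balanced training partition and
evaluated once on the untouched, imbalanced test partition at a fixed 0.5
probability threshold.  The leaderboard ranks by weighted F1, then
AUC-ROC, then name.

All confusion-matrix arithmetic is implemented directly (and
cross-checked against scikit-learn in the test suite); for binary
classification the support-weighted recall is identical to accuracy, and
that identity is asserted on every evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .preprocess import FeatureMatrix

MODEL_NAMES = (
    "forest",
    "extra_random_trees",
    "gradient_boosting",
    "xgboost_variant",
    "lightgbm_variant",
    "logistic",
    "knn",
    "naive_bayes",
    "svm_rbf",
    "mlp",
    "deep_net",
)

#: human-readable leaderboard labels
DISPLAY_NAMES = {
    "forest": "Random Forest",
    "extra_random_trees": "Extra Trees",
    "gradient_boosting": "Gradient Boosting",
    "xgboost_variant": "XGBoost",
    "lightgbm_variant": "LightGBM",
    "logistic": "Logistic Regression",
    "knn": "K-Nearest Neighbors",
    "naive_bayes": "Naive Bayes",
    "svm_rbf": "SVM (RBF)",
    "mlp": "Multi-layer Perceptron",
    "deep_net": "Deep Neural Network",
}

#: default tuning grids (kept as data, not baked into estimator factories);
#: pass grids={} entries or tuned=False to train at the fixed defaults.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "forest": {"n_estimators": [100, 200]},
    "extra_random_trees": {"n_estimators": [100, 200]},
    "gradient_boosting": {"n_estimators": [100, 200]},
    "xgboost_variant": {"n_estimators": [100, 200]},
    "lightgbm_variant": {"n_estimators": [100, 200]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [5, 11, 21]},
    "naive_bayes": {},
    "svm_rbf": {"estimator__C": [0.1, 1.0, 10.0]},
    "mlp": {},
    "deep_net": {},
}


@dataclass
class ModelSpec:
    """One benchmark entry: a named estimator factory plus a tuning grid."""

    name: str
    factory: Callable[[], Any]
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 42

    def build(self) -> Any:
        return self.factory()


def _model_factories(seed: int) -> dict[str, Callable[[], Any]]:
    # fixed hyperparameters: forests capped at depth 15, boosting at depth 6
    # with learning rate 0.1, tree counts within [100, 200]; MLP hidden
    # layers (100, 50); deep net 128-64-32-16-1 with L2 regularization.
    # Neural models: 20% internal validation split, early-stopping patience
    # 20 epochs, batch size 32, adaptive learning-rate schedule.
    return {
        "forest": lambda: RandomForestClassifier(
            n_estimators=100, max_depth=15, random_state=seed, n_jobs=1
        ),
        "extra_random_trees": lambda: ExtraTreesClassifier(
            n_estimators=100, max_depth=15, random_state=seed, n_jobs=1
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            n_estimators=100, max_depth=6, learning_rate=0.1, random_state=seed
        ),
        "xgboost_variant": lambda: XGBClassifier(
            n_estimators=100, max_depth=6, learning_rate=0.1, random_state=seed,
            eval_metric="logloss", verbosity=0, n_jobs=1,
        ),
        "lightgbm_variant": lambda: LGBMClassifier(
            n_estimators=100, max_depth=6, learning_rate=0.1, random_state=seed,
            verbose=-1, n_jobs=1,
        ),
        "logistic": lambda: LogisticRegression(C=1.0, max_iter=2000, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5, n_jobs=1),
        "naive_bayes": lambda: GaussianNB(),
        # margin classifier: probabilities via sigmoid (Platt) calibration
        # fitted on training folds
        "svm_rbf": lambda: CalibratedClassifierCV(
            SVC(C=1.0, kernel="rbf", random_state=seed, cache_size=500),
            method="sigmoid", cv=5, ensemble=False,
        ),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(100, 50), activation="relu", solver="adam",
            batch_size=32, early_stopping=True, validation_fraction=0.2,
            n_iter_no_change=20, max_iter=300, random_state=seed,
        ),
        "deep_net": lambda: MLPClassifier(
            hidden_layer_sizes=(128, 64, 32, 16), activation="relu", solver="adam",
            alpha=1e-3, batch_size=32, early_stopping=True, validation_fraction=0.2,
            n_iter_no_change=20, max_iter=300, random_state=seed,
        ),
    }


def default_model_specs(
    seed: int = 42, tuned: bool = True, models=MODEL_NAMES
) -> list[ModelSpec]:
    """The 11 benchmark model specifications.

    ``tuned=False`` empties every grid, training each model once at its
    fixed hyperparameters.
    """
    factories = _model_factories(seed)
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model names: {sorted(unknown)}")
    return [
        ModelSpec(
            name=name,
            factory=factories[name],
            grid=dict(DEFAULT_GRIDS[name]) if tuned else {},
            seed=seed,
        )
        for name in models
    ]


# ---------------------------------------------------------------------------
# training


def tune_and_train(
    spec: ModelSpec, train: FeatureMatrix, cv_folds: int = 10, seed: int | None = None
) -> tuple[Any, dict[str, Any]]:
    """Fit one model, grid-searching by weighted F1 when the grid has >1 point.

    Exhaustive search over ``spec.grid`` under stratified
    ``cv_folds``-fold cross-validation on the training partition only,
    refit on the full training partition at the winning grid point.  A
    singleton (or empty) grid is identical to plain training at the fixed
    hyperparameters.
    """
    seed = spec.seed if seed is None else seed
    X = train.values.to_numpy(dtype=float)
    y = train.labels.to_numpy()
    grid_size = int(np.prod([len(v) for v in spec.grid.values()])) if spec.grid else 1
    if grid_size <= 1:
        model = spec.build()
        if spec.grid:
            model.set_params(**{k: v[0] for k, v in spec.grid.items()})
        model.fit(X, y)
        chosen = {k: v[0] for k, v in spec.grid.items()}
        return model, chosen
    counts = np.bincount(y)
    if counts[counts > 0].min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts[counts > 0].min()} rows < {cv_folds} folds; "
            "use fewer folds"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        spec.build(), spec.grid, scoring="f1_weighted", cv=cv, refit=True, n_jobs=1
    )
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        counts = (self.tn, self.fp, self.fn, self.tp)
        if any(c < 0 for c in counts):
            raise ValueError(f"counts must be non-negative: {counts}")
        if sum(counts) == 0:
            raise ValueError("confusion matrix total must be positive")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def supports(self) -> tuple[int, int]:
        """(negative support, positive support)."""
        return (self.tn + self.fp, self.fn + self.tp)


def predict_proba(model: Any, X: np.ndarray) -> np.ndarray:
    """Positive-class probabilities; silences LightGBM's synthetic
    ``Column_i`` feature-name mismatch warning on numpy input."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names", category=UserWarning
        )
        return np.asarray(model.predict_proba(X))[:, 1]


def _safe_div(num: float, den: float) -> float:
    """Exact ratio, or NaN (undefined) on a zero denominator."""
    return num / den if den != 0 else float("nan")


def _f1(precision: float, recall: float) -> float:
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def confusion_metrics(cm: ConfusionMatrix, supports: tuple[int, int] | None = None) -> dict:
    """All derived metrics from a 2x2 confusion matrix — pure arithmetic.

    Zero-denominator metrics are reported as NaN (undefined), never 0.
    Support-weighted recall equals accuracy by construction in the binary
    case; both are reported.
    """
    if supports is not None and tuple(supports) != cm.supports:
        raise ValueError(f"supports {supports} inconsistent with matrix {cm.supports}")
    n_neg, n_pos = cm.supports
    n = cm.total
    accuracy = _safe_div(cm.tp + cm.tn, n)
    sensitivity = _safe_div(cm.tp, cm.tp + cm.fn)  # recall, positive class
    specificity = _safe_div(cm.tn, cm.tn + cm.fp)  # recall, negative class
    ppv = _safe_div(cm.tp, cm.tp + cm.fp)  # precision, positive class
    npv = _safe_div(cm.tn, cm.tn + cm.fn)  # precision, negative class
    f1_pos = _f1(ppv, sensitivity)
    f1_neg = _f1(npv, specificity)

    def weighted(neg: float, pos: float) -> float:
        return _safe_div(n_neg * neg + n_pos * pos, n)

    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "ppv": ppv,
        "npv": npv,
        "f1_positive": f1_pos,
        "f1_negative": f1_neg,
        "weighted_precision": weighted(npv, ppv),
        "weighted_recall": weighted(specificity, sensitivity),
        "weighted_f1": weighted(f1_neg, f1_pos),
        "supports": {"negative": n_neg, "positive": n_pos},
    }


@dataclass
class MetricsRow:
    model: str
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    auc_roc: float
    confusion: ConfusionMatrix
    per_class: dict
    chosen_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # binary identity: support-weighted recall is accuracy
        if not math.isclose(self.weighted_recall, self.accuracy, abs_tol=1e-12):
            raise AssertionError(
                f"weighted recall {self.weighted_recall} != accuracy {self.accuracy}"
            )


def evaluate(
    model: Any, test: FeatureMatrix, name: str = "model", threshold: float = 0.5
) -> MetricsRow:
    """Score a fitted model on the held-out test partition.

    Class predictions at the given probability threshold; AUC-ROC from
    positive-class scores by the rank (trapezoid) method with midrank tie
    handling.
    """
    y = test.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: test labels contain a single class")
    proba = predict_proba(model, test.values.to_numpy(dtype=float))
    pred = (proba >= threshold).astype(int)
    cm = ConfusionMatrix(
        tn=int(np.sum((y == 0) & (pred == 0))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == 0))),
        tp=int(np.sum((y == 1) & (pred == 1))),
    )
    m = confusion_metrics(cm)
    return MetricsRow(
        model=name,
        accuracy=m["accuracy"],
        weighted_precision=m["weighted_precision"],
        weighted_recall=m["weighted_recall"],
        weighted_f1=m["weighted_f1"],
        auc_roc=float(roc_auc_score(y, proba)),
        confusion=cm,
        per_class={
            "precision": {"negative": m["npv"], "positive": m["ppv"]},
            "recall": {"negative": m["specificity"], "positive": m["sensitivity"]},
            "f1": {"negative": m["f1_negative"], "positive": m["f1_positive"]},
            "support": m["supports"],
        },
    )


def rank_models(rows: list[MetricsRow]) -> list[MetricsRow]:
    """Leaderboard: weighted F1 descending, ties by AUC-ROC then name."""
    if not rows:
        raise ValueError("no metric rows to rank")
    return sorted(rows, key=lambda r: (-r.weighted_f1, -r.auc_roc, r.model))


def run_benchmark(
    train: FeatureMatrix,
    test: FeatureMatrix,
    specs: list[ModelSpec] | None = None,
    cv_folds: int = 10,
    seed: int = 42,
) -> tuple[list[MetricsRow], dict[str, Any]]:
    """Train and evaluate every spec; returns (leaderboard, fitted models)."""
    if specs is None:
        specs = default_model_specs(seed=seed)
    rows = []
    models: dict[str, Any] = {}
    for spec in specs:
        model, chosen = tune_and_train(spec, train, cv_folds=cv_folds, seed=seed)
        row = evaluate(model, test, name=spec.name)
        row.chosen_params = chosen
        rows.append(row)
        models[spec.name] = model
    return rank_models(rows), models


def leaderboard_frame(rows: list[MetricsRow]):
    """Leaderboard as a DataFrame shaped like the benchmark summary table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "model": DISPLAY_NAMES.get(r.model, r.model),
                "accuracy": r.accuracy,
                "precision": r.weighted_precision,
                "recall": r.weighted_recall,
                "f1": r.weighted_f1,
                "auc_roc": r.auc_roc,
            }
            for r in rows
        ]
    )
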