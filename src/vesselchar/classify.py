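"""Supervised classification of feature vectors with cross-validated grids.

Four classifier kinds are supported: a degree-1 polynomial-kernel SVM
(``svm_poly``, for linearly separable feature spaces), an RBF-kernel SVM
(``svm_rbf``), k-nearest neighbours (``knn``, Euclidean metric) and a
random forest (``rf``).  Hyperparameters are optimized by exhaustive
grid search over the standard ranges — C and γ from 0.01 to 1000 in
decade steps, k from 1 to 10, tree depth 1–10 with 10–100 trees in
steps of 5 — using stratified tenfold cross-validation; evaluation
reports the pooled out-of-fold confusion matrix with accuracy,
class-weighted one-vs-rest sensitivity/specificity and ROC AUC.

SVMs resolve multi-class problems by pairwise (one-vs-one) voting;
features are standardized (fit on training folds only) for the SVMs and
kNN.  Reference hyperparameters (``REFERENCE_PARAMS``) ship the optima
reported for the clinical feature tables: C = 1 (poly), C = 1 with
γ = 0.01 (RBF), k = 3, depth 8 with 50 trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CLASSIFIER_KINDS",
    "DEFAULT_GRIDS",
    "REFERENCE_PARAMS",
    "EvalReport",
    "confusion_metrics",
    "make_estimator",
    "grid_search_cv",
    "evaluate_cv",
]

CLASSIFIER_KINDS: tuple[str, ...] = ("svm_poly", "svm_rbf", "knn", "rf")

_DECADES = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "svm_poly": {"C": _DECADES},
    "svm_rbf": {"C": _DECADES, "gamma": _DECADES},
    "knn": {"n_neighbors": tuple(range(1, 11))},
    "rf": {
        "max_depth": tuple(range(1, 11)),
        "n_estimators": tuple(range(10, 101, 5)),
    },
}

REFERENCE_PARAMS: dict[str, dict[str, float | int]] = {
    "svm_poly": {"C": 1.0},
    "svm_rbf": {"C": 1.0, "gamma": 0.01},
    "knn": {"n_neighbors": 3},
    "rf": {"max_depth": 8, "n_estimators": 50},
}


@dataclass(frozen=True)
class EvalReport:
    """Pooled cross-validation outcome of one classifier."""

    kind: str
    params: dict
    classes: tuple[str, ...]
    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    fold_accuracies: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": self.params,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "fold_accuracies": list(self.fold_accuracies),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def make_estimator(kind: str, seed: int = 0, **params):
    """Build the (optionally standardized) estimator pipeline of a kind."""
    if kind == "svm_poly":
        clf = SVC(kernel="poly", degree=1, coef0=0.0, gamma="scale",
                  decision_function_shape="ovr", **params)
    elif kind == "svm_rbf":
        clf = SVC(kernel="rbf", decision_function_shape="ovr", **params)
    elif kind == "knn":
        clf = KNeighborsClassifier(metric="euclidean", **params)
    elif kind == "rf":
        clf = RandomForestClassifier(random_state=seed, **params)
    else:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    if kind == "rf":
        return Pipeline([("clf", clf)])
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _grid_points(grid: dict[str, tuple]):
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def grid_search_cv(
    X: np.ndarray,
    y,
    kind: str,
    seed: int = 0,
    folds: int = 10,
    grid: dict[str, tuple] | None = None,
) -> dict:
    """Exhaustive hyperparameter search by stratified k-fold CV accuracy.

    The grid is scanned in ascending parameter order and a candidate
    replaces the incumbent only on a strict improvement, so ties resolve
    toward the least complex model (smallest C/γ/k/depth).
    """
    grid = DEFAULT_GRIDS[kind] if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_params, best_score = None, -np.inf
    for params in _grid_points(grid):
        est = make_estimator(kind, seed=seed, **params)
        score = cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean()
        if score > best_score:
            best_params, best_score = params, score
    return best_params


def confusion_metrics(cm: np.ndarray) -> tuple[float, float, float]:
    """Accuracy and class-weighted one-vs-rest sensitivity/specificity.

    ``cm[i, j]`` counts samples of true class i predicted as class j.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    accuracy = float(np.trace(cm)) / total
    weights = cm.sum(axis=1) / total
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    sensitivity = float(np.sum(weights * tp / np.maximum(tp + fn, 1)))
    specificity = float(np.sum(weights * tn / np.maximum(tn + fp, 1)))
    return accuracy, sensitivity, specificity


def _scores_for_auc(est, X: np.ndarray) -> np.ndarray:
    clf = est.named_steps["clf"]
    if hasattr(clf, "decision_function"):
        return est.decision_function(X)
    return est.predict_proba(X)


def evaluate_cv(
    X: np.ndarray,
    y,
    kind: str,
    params: dict | None = None,
    seed: int = 0,
    folds: int = 10,
) -> EvalReport:
    """Stratified k-fold evaluation with a pooled confusion matrix.

    Out-of-fold predictions of all folds are pooled into one confusion
    matrix; accuracy is its trace over the total, sensitivity and
    specificity are class-frequency-weighted one-vs-rest averages, and
    AUC is the class-weighted one-vs-rest area under the ROC built from
    decision scores (SVM) or class probabilities (kNN, forest).
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind: {kind!r}")
    params = REFERENCE_PARAMS[kind] if params is None else params
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    n_score_cols = 1 if len(classes) == 2 else len(classes)
    scores = np.zeros((len(y), n_score_cols))
    fold_acc = []
    for train, test in cv.split(X, y):
        est = make_estimator(kind, seed=seed, **params)
        est.fit(X[train], y[train])
        y_pred[test] = est.predict(X[test])
        s = _scores_for_auc(est, X[test])
        if len(classes) == 2:
            scores[test, 0] = s[:, 1] if s.ndim == 2 else s
        else:
            scores[test] = s
        fold_acc.append(float(np.mean(y_pred[test] == y[test])))
    cm = confusion_matrix(y, y_pred, labels=classes)
    accuracy, sensitivity, specificity = confusion_metrics(cm)
    weights = cm.sum(axis=1) / cm.sum()
    if len(classes) == 2:
        auc = float(roc_auc_score(y == classes[1], scores[:, 0]))
    else:
        per_class = [
            roc_auc_score(y == c, scores[:, j]) for j, c in enumerate(classes)
        ]
        auc = float(np.sum(weights * np.asarray(per_class)))
    return EvalReport(
        kind=kind,
        params=dict(params),
        classes=tuple(str(c) for c in classes),
        confusion=cm,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        fold_accuracies=tuple(fold_acc),
    )
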