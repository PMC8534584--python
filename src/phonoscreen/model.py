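"""Classifier configurations, tuning, and the study's performance metrics.

Three off-the-shelf classifiers are tuned by inner cross-validation on
balanced accuracy: an RBF-kernel SVM over a (C, gamma) power-of-two grid
with per-feature [-1, 1] scaling, random forests over tree-count and
feature-subsampling multipliers, and AdaBoost over a learning-rate grid
with 1000 shallow-tree weak learners.  Evaluation reports sensitivity
(PwP = label 1 positive), specificity, their mean (balanced accuracy) and
the full confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import PhonoscreenError


# ---------------------------------------------------------------------------
# configurations


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM with [-1, 1] feature scaling fit on training data only."""

    C_grid: tuple = tuple(2.0**k for k in range(-5, 16, 2))      # 11 values
    w_grid: tuple = tuple(2.0**k for k in range(-15, 4, 2))      # 10 values
    fixed: dict = field(default_factory=lambda: {"C": 2.0, "gamma": 2.0**-5})

    name = "svm"

    def grid(self):
        return [{"C": c, "gamma": w} for c in self.C_grid for w in self.w_grid]

    def build(self, params: dict, n_features: int | None = None) -> Any:
        return SVC(kernel="rbf", **params)


@dataclass(frozen=True)
class ForestConfig:
    """Random forest over tree counts and feature-subsampling multipliers."""

    n_trees: tuple = (500, 1000)
    feature_subset_multiplier: tuple = (0.5, 1.0, 2.0)
    seed: int = 0
    fixed: dict = field(default_factory=lambda: {
        "n_estimators": 500, "multiplier": 1.0})

    name = "forest"

    def grid(self):
        return [{"n_estimators": n, "multiplier": m}
                for n in self.n_trees for m in self.feature_subset_multiplier]

    def build(self, params: dict, n_features: int | None = None) -> Any:
        p = dict(params)
        mult = p.pop("multiplier", 1.0)
        if n_features is None:
            mf: int | str = "sqrt"
        else:
            mf = max(1, min(n_features,
                            int(round(mult * math.sqrt(n_features)))))
        return RandomForestClassifier(
            max_features=mf, random_state=self.seed, n_jobs=1, **p)


@dataclass(frozen=True)
class BoostConfig:
    """AdaBoost with shallow-tree weak learners and a learning-rate grid."""

    learning_rate_grid: tuple = (0.01, 0.03, 0.05, 0.1, 0.3, 0.5)
    n_estimators: int = 1000
    base_depth: int = 2
    seed: int = 0
    fixed: dict = field(default_factory=lambda: {"learning_rate": 0.1})

    name = "boost"

    def grid(self):
        return [{"learning_rate": lr} for lr in self.learning_rate_grid]

    def build(self, params: dict, n_features: int | None = None) -> Any:
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=self.base_depth),
            n_estimators=self.n_estimators, random_state=self.seed, **params)


# ---------------------------------------------------------------------------
# scaling


@dataclass
class RangeScaler:
    """Per-feature linear map onto [-1, 1], fit on training data only."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "RangeScaler":
        X = np.asarray(X, dtype=float)
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.hi - self.lo
        span = np.where(span == 0, 1.0, span)
        return 2.0 * (X - self.lo) / span - 1.0


# ---------------------------------------------------------------------------
# evaluation report


@dataclass
class EvalReport:
    sensitivity: float          # percent
    specificity: float          # percent
    balanced_accuracy: float    # percent
    confusion: dict             # keys tp, fn, fp, tn
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.sensitivity) and np.isfinite(self.specificity):
            assert abs(self.balanced_accuracy
                       - (self.sensitivity + self.specificity) / 2.0) < 1e-9


def report_from_counts(tp: int, fn: int, fp: int, tn: int) -> EvalReport:
    """Build an EvalReport from confusion counts (PwP positive)."""
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    ba = (sens + spec) / 2.0
    return EvalReport(sensitivity=sens, specificity=spec,
                      balanced_accuracy=ba,
                      confusion={"tp": tp, "fn": fn, "fp": fp, "tn": tn})


def balanced_accuracy_from_rates(sensitivity: float,
                                 specificity: float) -> float:
    """Balanced accuracy identity used throughout reporting (percent)."""
    return (sensitivity + specificity) / 2.0


# ---------------------------------------------------------------------------
# training / evaluation


@dataclass
class TrainedModel:
    kind: str
    estimator: Any = field(repr=False)
    scaler: RangeScaler | None
    feature_names: list[str] | None
    params: dict
    train_fingerprint: int = 0

    def predict(self, X: np.ndarray,
                feature_names: list[str] | None = None) -> np.ndarray:
        if (feature_names is not None and self.feature_names is not None
                and list(feature_names) != list(self.feature_names)):
            raise PhonoscreenError("feature-name manifest mismatch")
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.estimator.predict(X)


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred != 1)))
    fp = int(np.sum((y_true != 1) & (y_pred == 1)))
    tn = int(np.sum((y_true != 1) & (y_pred != 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return (sens + spec) / 2.0


def _stratified_folds(y: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.asarray(sorted(f)) for f in folds]


def fit_model(X: np.ndarray, y: np.ndarray, config,
              params: dict | None = None,
              feature_names: list[str] | None = None) -> TrainedModel:
    """Fit one classifier with given (or config-default) hyper-parameters."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise PhonoscreenError("single-class training data")
    params = dict(config.fixed if params is None else params)
    scaler = RangeScaler.fit(X) if config.name == "svm" else None
    Xs = scaler.transform(X) if scaler is not None else np.asarray(X, dtype=float)
    est = config.build(params, n_features=Xs.shape[1])
    est.fit(Xs, y)
    return TrainedModel(kind=config.name, estimator=est, scaler=scaler,
                        feature_names=list(feature_names) if feature_names else None,
                        params=params,
                        train_fingerprint=hash(np.asarray(X, dtype=float).tobytes()))


def tune_and_train(X: np.ndarray, y: np.ndarray, config,
                   inner_cv_folds: int = 5, seed: int = 0,
                   feature_names: list[str] | None = None) -> TrainedModel:
    """Exhaustive grid search by inner CV on balanced accuracy, then refit.

    Ties break toward smaller C / larger gamma for the SVM (first match in
    the documented grid order for the other classifiers).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise PhonoscreenError("single-class training data")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, inner_cv_folds, rng)
    grid = config.grid()
    mean_scores = np.zeros(len(grid))
    for gi, params in enumerate(grid):
        scores = []
        for f in range(inner_cv_folds):
            test_idx = folds[f]
            train_idx = np.concatenate([folds[g] for g in range(inner_cv_folds)
                                        if g != f])
            if len(np.unique(y[train_idx])) < 2 or len(test_idx) == 0:
                continue
            m = fit_model(X[train_idx], y[train_idx], config, params)
            scores.append(_balanced_accuracy(y[test_idx],
                                             m.predict(X[test_idx])))
        mean_scores[gi] = np.mean(scores) if scores else 0.0
    # tie-break: smaller C then larger gamma (grid() enumerates C outer
    # ascending, gamma inner ascending, so prefer the LAST gamma at the
    # first maximal C block)
    best_score = mean_scores.max()
    best_idx = [i for i, s in enumerate(mean_scores)
                if abs(s - best_score) < 1e-12]
    if config.name == "svm":
        keyf = lambda i: (grid[i]["C"], -grid[i]["gamma"])
        best = min(best_idx, key=keyf)
    else:
        best = best_idx[0]
    model = fit_model(X, y, config, grid[best], feature_names=feature_names)
    return model


def evaluate(model: TrainedModel, X_test: np.ndarray, y_test: np.ndarray,
             feature_names: list[str] | None = None) -> EvalReport:
    """Confusion-matrix evaluation with PwP (label 1) as positive class.

    The stored training-time scaling is applied to the test data; the guard
    in :meth:`TrainedModel.predict` refuses mismatched feature manifests.
    """
    y_pred = model.predict(X_test, feature_names)
    y_test = np.asarray(y_test)
    tp = int(np.sum((y_test == 1) & (y_pred == 1)))
    fn = int(np.sum((y_test == 1) & (y_pred != 1)))
    fp = int(np.sum((y_test != 1) & (y_pred == 1)))
    tn = int(np.sum((y_test != 1) & (y_pred != 1)))
    return report_from_counts(tp, fn, fp, tn)
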