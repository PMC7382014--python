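"""LASSO feature compression and random-forest keypoint importance.

The compressor is L1-penalized *linear* regression on the 0/1 label
(an L1-logistic variant is available behind a flag); a feature survives
iff its fitted weight is nonzero. ``lasso_sweep`` tracks the retained
set and downstream LR/SVM accuracy across a penalty grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .trajectory_features import FEATURE_NAMES, feature_matrix

#: weights with |w| below this are treated as exactly zero
WEIGHT_TOL = 1e-8

DEFAULT_ALPHA_GRID = tuple(
    sorted(set(np.geomspace(1e-4, 1e-1, 30).tolist()) | {0.004})
)


@dataclass(frozen=True)
class LassoSweepResult:
    """Per-alpha retained features and downstream accuracies."""

    table: pd.DataFrame          # columns: alpha, n_retained, lr_accuracy, svm_accuracy, ...
    retained: dict[float, list[str]]


@dataclass(frozen=True)
class KeypointImportance:
    """Aggregated random-forest importance per key point."""

    scores: pd.Series            # index: point name, impurity importance summed over 8 features
    ranking: list[str]           # point names, most important first


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0            # constant columns stay zero after centering
    return (X - mu) / sd


def lasso_select(
    table: pd.DataFrame,
    alpha: float,
    logistic: bool = False,
    seed: int = 0,
) -> list[str]:
    """Names of features with nonzero weight under an L1 penalty ``alpha``.

    Features are standardized (zero mean, unit variance) before the fit.
    """
    X, y, _, names = feature_matrix(table)
    if X.shape[0] == 0:
        raise ValueError("empty feature table")
    Xs = _standardize(X)
    if logistic:
        # sklearn parametrizes logistic L1 by C = 1 / (n * alpha)
        C = 1.0 / max(alpha * X.shape[0], 1e-12)
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear",
            random_state=seed, max_iter=5000,
        )
        model.fit(Xs, y)
        w = model.coef_.ravel()
    else:
        model = Lasso(alpha=max(alpha, 1e-12), max_iter=50_000, tol=1e-6)
        model.fit(Xs, y.astype(float))
        w = model.coef_
    return [n for n, wi in zip(names, w) if abs(wi) > WEIGHT_TOL]


def _grouped_accuracy(X, y, groups, model_factory, n_splits, seed) -> float:
    """Subject-grouped stratified CV accuracy; majority-class baseline on 0 features."""
    if X.shape[1] == 0:
        majority = np.bincount(y).argmax()
        return float(np.mean(y == majority))
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for train, test in cv.split(X, y, groups):
        model = model_factory()
        model.fit(X[train], y[train])
        correct += int(np.sum(model.predict(X[test]) == y[test]))
    return correct / len(y)


def _training_accuracy(X, y, model_factory) -> float:
    if X.shape[1] == 0:
        majority = np.bincount(y).argmax()
        return float(np.mean(y == majority))
    model = model_factory()
    model.fit(X, y)
    return float(np.mean(model.predict(X) == y))


def lasso_sweep(
    table: pd.DataFrame,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_splits: int = 5,
    seed: int = 0,
    logistic: bool = False,
) -> LassoSweepResult:
    """Sweep the L1 penalty; per alpha report retained count and LR/SVM accuracy.

    Accuracies are subject-grouped ``n_splits``-fold cross-validated on
    the retained features; training-set accuracies are reported
    alongside (``*_train_accuracy`` columns).
    """
    X, y, groups, names = feature_matrix(table)
    name_idx = {n: i for i, n in enumerate(names)}
    Xs = _standardize(X)

    def lr_factory():
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=5000, random_state=seed)
        )

    def svm_factory():
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))

    rows = []
    retained: dict[float, list[str]] = {}
    for alpha in alpha_grid:
        kept = lasso_select(table, alpha, logistic=logistic, seed=seed)
        retained[float(alpha)] = kept
        cols = [name_idx[n] for n in kept]
        Xk = Xs[:, cols]
        rows.append(
            {
                "alpha": float(alpha),
                "n_retained": len(kept),
                "lr_accuracy": _grouped_accuracy(Xk, y, groups, lr_factory, n_splits, seed),
                "svm_accuracy": _grouped_accuracy(Xk, y, groups, svm_factory, n_splits, seed),
                "lr_train_accuracy": _training_accuracy(Xk, y, lr_factory),
                "svm_train_accuracy": _training_accuracy(Xk, y, svm_factory),
            }
        )
    return LassoSweepResult(table=pd.DataFrame(rows), retained=retained)


def rf_keypoint_importance(
    table: pd.DataFrame, n_estimators: int = 100, seed: int = 0
) -> KeypointImportance:
    """Random-forest impurity importances summed over each key point's 8 features."""
    X, y, _, names = feature_matrix(table)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X, y)
    per_feature = pd.Series(rf.feature_importances_, index=names)
    point = per_feature.index.str.rsplit("__", n=1).str[0]
    scores = per_feature.groupby(point).sum()
    # preserve schema point order in the index, ranking by score
    order = []
    seen = set()
    for n in names:
        p = n.rsplit("__", 1)[0]
        if p not in seen:
            seen.add(p)
            order.append(p)
    scores = scores.reindex(order)
    ranking = scores.sort_values(ascending=False, kind="stable").index.tolist()
    return KeypointImportance(scores=scores, ranking=ranking)
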