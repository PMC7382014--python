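"""Classical classifiers on the feature table.

LR, RBF-kernel SVM, decision tree and random forest are evaluated with
subject-grouped stratified k-fold cross-validation; precision, recall
and F1 are reported for the PD-positive class, pooled over folds.
Grouping by subject matters: each subject contributes repeated records,
and letting them straddle folds leaks identity into the test folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .trajectory_features import feature_matrix

ALGORITHMS = ("lr", "svm", "dt", "rf")


def _make_model(algorithm: str, seed: int):
    if algorithm == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=5000, random_state=seed)
        )
    if algorithm == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


@dataclass(frozen=True)
class ClassificationReport:
    """Pooled precision/recall/F1 per algorithm plus per-fold detail."""

    metrics: pd.DataFrame                       # index: algorithm; precision/recall/f1
    confusion: dict[str, dict[str, int]]        # per algorithm: tp/fp/fn/tn
    folds: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="index"),
            "confusion": self.confusion,
        }


def evaluate_classifiers(
    table: pd.DataFrame,
    algorithms=ALGORITHMS,
    n_splits: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Subject-grouped stratified CV of the requested algorithms.

    Predictions are pooled over folds; metrics use the PD class as
    positive. Raises if any fold's training split is single-class.
    """
    X, y, groups, _ = feature_matrix(table)
    if len(np.unique(groups[y == 1])) < 2 or len(np.unique(groups[y == 0])) < 2:
        raise ValueError("need at least 2 subjects per class")
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y, groups))
    for k, (train, _) in enumerate(splits):
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {k} has a single-class training split")

    rows = {}
    confusion = {}
    fold_rows = []
    for algorithm in algorithms:
        pred = np.empty_like(y)
        for k, (train, test) in enumerate(splits):
            model = _make_model(algorithm, seed)
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
            fold_tp = int(np.sum((pred[test] == 1) & (y[test] == 1)))
            fold_rows.append(
                {
                    "algorithm": algorithm,
                    "fold": k,
                    "n_test": len(test),
                    "accuracy": float(np.mean(pred[test] == y[test])),
                    "tp": fold_tp,
                }
            )
        tp = int(np.sum((pred == 1) & (y == 1)))
        fp = int(np.sum((pred == 1) & (y == 0)))
        fn = int(np.sum((pred == 0) & (y == 1)))
        tn = int(np.sum((pred == 0) & (y == 0)))
        confusion[algorithm] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        rows[algorithm] = metrics_from_confusion(tp, fp, fn, tn)
    metrics = pd.DataFrame(rows).T[["precision", "recall", "f1"]]
    metrics.index.name = "algorithm"
    return ClassificationReport(
        metrics=metrics, confusion=confusion, folds=pd.DataFrame(fold_rows)
    )


def fit_final(
    table: pd.DataFrame, algorithm: str, seed: int, out_path: str | Path
) -> Path:
    """Fit on all records and serialize model + column/label metadata.

    The saved artifact reloads with :func:`load_final`; prediction on a
    table with permuted columns matches because columns are re-aligned
    by name.
    """
    X, y, _, names = feature_matrix(table)
    model = _make_model(algorithm, seed)
    model.fit(X, y)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, out_path)
    meta = {"algorithm": algorithm, "seed": seed, "feature_columns": names}
    out_path.with_suffix(out_path.suffix + ".meta.json").write_text(json.dumps(meta))
    return out_path


def load_final(path: str | Path):
    path = Path(path)
    model = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return model, meta


def predict_final(path: str | Path, table: pd.DataFrame) -> np.ndarray:
    """Predict labels (1 = PD) using a serialized model, aligning columns by name."""
    model, meta = load_final(path)
    X = table[meta["feature_columns"]].to_numpy(dtype=float)
    return model.predict(X)
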