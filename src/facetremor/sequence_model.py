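"""First-order differenced keypoint series and recurrent classification.

Each record's relative-coordinate trajectories are turned into a
(N-1) x 212 array of per-frame differences (delta_i = value_{i-1} -
value_i, two channels per key point), then classified with a recurrent
network: a single LSTM (or simple tanh RNN) layer whose final hidden
state feeds a linear softmax head.

The recurrent nets are implemented directly on NumPy (forward +
backpropagation-through-time); the deliberately small scale — dozens of
records, ~50 steps — does not justify a deep-learning framework, and
training is exactly reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, StratifiedGroupKFold

from .diagnosis_models import ClassificationReport, metrics_from_confusion
from .relative_coords import RelativeSequence


@dataclass(frozen=True)
class DiffSeries:
    """Differenced series for one record: (N-1) steps x (2 * n_points) channels.

    Channel order is fixed: point 0 delta-x, point 0 delta-y, point 1
    delta-x, ... following schema point order. The sign convention is
    delta_i = value_{i-1} - value_i.
    """

    values: np.ndarray
    label: str
    record_id: str
    subject_id: str

    @property
    def n_steps(self) -> int:
        return int(self.values.shape[0])


def difference(rel: RelativeSequence) -> DiffSeries:
    """First-order difference of a record's relative coordinates."""
    if rel.n_frames < 2:
        raise ValueError("differencing needs at least 2 frames")
    coords = rel.coords                      # (N, P, 2)
    diffs = coords[:-1] - coords[1:]         # delta_i = value_{i-1} - value_i
    values = diffs.reshape(diffs.shape[0], -1)
    return DiffSeries(
        values=values,
        label=rel.label,
        record_id=rel.record_id,
        subject_id=rel.subject_id,
    )


def undifference(series: DiffSeries, first_frame: np.ndarray) -> np.ndarray:
    """Invert :func:`difference` given the first frame's (P, 2) coordinates."""
    flat0 = np.asarray(first_frame, dtype=float).reshape(-1)
    flat = np.vstack([flat0, flat0 - np.cumsum(series.values, axis=0)])
    return flat.reshape(flat.shape[0], -1, 2)


def pad_and_stack(data: list[DiffSeries]):
    """Zero-pad variable-length series to (B, T_max, C) with a (B, T) mask."""
    if not data:
        raise ValueError("no series supplied")
    t_max = max(s.n_steps for s in data)
    n_ch = data[0].values.shape[1]
    X = np.zeros((len(data), t_max, n_ch))
    mask = np.zeros((len(data), t_max))
    for i, s in enumerate(data):
        if s.values.shape[1] != n_ch:
            raise ValueError("inconsistent channel counts across records")
        X[i, : s.n_steps] = s.values
        mask[i, : s.n_steps] = 1.0
    y = np.array([1 if s.label == "PD" else 0 for s in data])
    groups = np.array([s.subject_id for s in data])
    return X, mask, y, groups


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class SequenceClassifier:
    """Single-layer LSTM / simple-RNN binary classifier (NumPy BPTT).

    Full-batch Adam on softmax cross-entropy of the final masked hidden
    state. The output bias is initialized to the training-class log
    priors, so an untrained model (``epochs=0``) predicts the majority
    class.
    """

    def __init__(
        self,
        arch: str = "lstm",
        hidden: int = 32,
        lr: float = 5e-3,
        epochs: int = 60,
        patience: int = 8,
        seed: int = 0,
    ):
        if arch not in ("lstm", "rnn"):
            raise ValueError(f"unknown architecture {arch!r}")
        self.arch = arch
        self.hidden = hidden
        self.lr = lr
        self.epochs = epochs
        self.patience = patience
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self._norm: tuple[np.ndarray, np.ndarray] | None = None

    # ----- forward -------------------------------------------------------

    def _init_params(self, n_ch: int, y: np.ndarray) -> None:
        rng = np.random.default_rng(self.seed)
        H = self.hidden
        gates = 4 * H if self.arch == "lstm" else H
        scale = 1.0 / np.sqrt(n_ch + H)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_ch + H, gates)),
            "b": np.zeros(gates),
            "Wy": np.zeros((H, 2)),
            "by": np.log(np.bincount(y, minlength=2) / len(y) + 1e-12),
        }
        if self.arch == "lstm":
            self.params["b"][H : 2 * H] = 1.0  # forget-gate bias

    def _forward(self, X: np.ndarray, mask: np.ndarray, cache: bool = False):
        B, T, _ = X.shape
        H = self.hidden
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        for t in range(T):
            m = mask[:, t][:, None]
            xh = np.concatenate([X[:, t], h], axis=1)
            z = xh @ W + b
            if self.arch == "lstm":
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                if cache:
                    caches.append((xh, i, f, g, o, c, c_new, tc, m, h))
                c = m * c_new + (1 - m) * c
            else:
                h_new = np.tanh(z)
                if cache:
                    caches.append((xh, h_new, m, h))
            h = m * h_new + (1 - m) * h
        logits = h @ self.params["Wy"] + self.params["by"]
        return (logits, h, caches) if cache else (logits, h, None)

    # ----- backward ------------------------------------------------------

    def _backward(self, X, mask, caches, dh, h_final):
        B, T, C = X.shape
        H = self.hidden
        W = self.params["W"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            if self.arch == "lstm":
                xh, i, f, g, o, c_prev, c_new, tc, m, h_prev = caches[t]
                dh_new = m * dh
                dc_new = m * dc
                do = dh_new * tc
                dc_new = dc_new + dh_new * o * (1 - tc**2)
                di = dc_new * g
                df = dc_new * c_prev
                dg = dc_new * i
                dc = dc_new * f + (1 - m) * dc
                dz = np.concatenate(
                    [
                        di * i * (1 - i),
                        df * f * (1 - f),
                        dg * (1 - g**2),
                        do * o * (1 - o),
                    ],
                    axis=1,
                )
            else:
                xh, h_new, m, h_prev = caches[t]
                dh_new = m * dh
                dz = dh_new * (1 - h_new**2)
            grads["W"] += xh.T @ dz
            grads["b"] += dz.sum(axis=0)
            dxh = dz @ W.T
            dh = dxh[:, C:] + (1 - m) * dh
        return grads

    # ----- training ------------------------------------------------------

    def _loss_and_grads(self, X, mask, y):
        logits, h, caches = self._forward(X, mask, cache=True)
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        B = len(y)
        loss = -np.log(probs[np.arange(B), y] + 1e-12).mean()
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = self._backward(X, mask, caches, dlogits @ self.params["Wy"].T, h)
        grads["Wy"] = h.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        return loss, grads

    def _eval_loss(self, X, mask, y):
        logits, _, _ = self._forward(X, mask)
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())

    def fit(self, X, mask, y, groups=None) -> "SequenceClassifier":
        X = np.asarray(X, dtype=float)
        mask = np.asarray(mask, dtype=float)
        y = np.asarray(y, dtype=int)
        mu = X[mask.astype(bool)].mean(axis=0)
        sd = X[mask.astype(bool)].std(axis=0)
        sd[sd == 0] = 1.0
        self._norm = (mu, sd)
        Xn = (X - mu) / sd * mask[:, :, None]
        self._init_params(X.shape[2], y)
        if self.epochs == 0:
            return self

        # grouped validation split for early stopping
        if groups is not None and len(np.unique(groups)) >= 5:
            splitter = GroupShuffleSplit(n_splits=1, test_size=0.2, random_state=self.seed)
            tr, va = next(splitter.split(Xn, y, groups))
            if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
                tr, va = np.arange(len(y)), np.arange(len(y))
        else:
            tr, va = np.arange(len(y)), np.arange(len(y))

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        bad = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        for step in range(1, self.epochs + 1):
            _, grads = self._loss_and_grads(Xn[tr], mask[tr], y[tr])
            for k in self.params:
                np.clip(grads[k], -5.0, 5.0, out=grads[k])
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                mhat = adam_m[k] / (1 - b1**step)
                vhat = adam_v[k] / (1 - b2**step)
                self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
            val_loss = self._eval_loss(Xn[va], mask[va], y[va])
            if val_loss < best_loss - 1e-5:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        self.params = best_params
        return self

    def predict(self, X, mask) -> np.ndarray:
        if self._norm is None:
            raise RuntimeError("classifier is not fitted")
        mu, sd = self._norm
        Xn = (np.asarray(X, dtype=float) - mu) / sd * np.asarray(mask, dtype=float)[:, :, None]
        logits, _, _ = self._forward(Xn, np.asarray(mask, dtype=float))
        return logits.argmax(axis=1)


def train_sequence_classifier(
    data: list[DiffSeries],
    arch: str = "lstm",
    seed: int = 0,
    n_splits: int = 3,
    hidden: int = 32,
    epochs: int = 60,
    lr: float = 5e-3,
    refit: bool = True,
):
    """Grouped-CV evaluation of a recurrent classifier on differenced series.

    Returns ``(model, report)`` where the report pools predictions over
    subject-grouped stratified folds and the model — when ``refit`` — is
    trained on all records.
    """
    X, mask, y, groups = pad_and_stack(data)
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("need at least 2 records per class")
    cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    fold_rows = []
    for k, (train, test) in enumerate(cv.split(X, y, groups)):
        clf = SequenceClassifier(
            arch=arch, hidden=hidden, lr=lr, epochs=epochs, seed=seed
        )
        clf.fit(X[train], mask[train], y[train], groups[train])
        pred[test] = clf.predict(X[test], mask[test])
        fold_rows.append(
            {
                "algorithm": arch,
                "fold": k,
                "n_test": len(test),
                "accuracy": float(np.mean(pred[test] == y[test])),
            }
        )
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    metrics = pd.DataFrame(
        {arch: metrics_from_confusion(tp, fp, fn, tn)}
    ).T[["precision", "recall", "f1"]]
    metrics.index.name = "algorithm"
    report = ClassificationReport(
        metrics=metrics,
        confusion={arch: {"tp": tp, "fp": fp, "fn": fn, "tn": tn}},
        folds=pd.DataFrame(fold_rows),
    )
    model = None
    if refit:
        model = SequenceClassifier(arch=arch, hidden=hidden, lr=lr, epochs=epochs, seed=seed)
        model.fit(X, mask, y, groups)
    return model, report
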