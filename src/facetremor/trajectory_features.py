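"""Per-keypoint trajectory features.

Eight scalar features per key point: four expression-amplitude features
(x/y range and covariance on relative coordinates, plus covariance on
absolute coordinates) and four positional-jitter tremor features
(jitter_abs / jitter_ppq5 / jitter_rap / jitter_ddp) on absolute
coordinates. With a 106-point schema each record yields
106 x 8 = 848 feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import LandmarkSequence
from .relative_coords import RelativeSequence, to_relative_sequence

#: canonical per-point feature order; column names are "{point}__{feature}"
FEATURE_NAMES = (
    "R_x_max",
    "R_y_max",
    "cov_rel",
    "cov_abs",
    "jitter_abs",
    "jitter_ppq5",
    "jitter_rap",
    "jitter_ddp",
)

AMPLITUDE_FEATURES = FEATURE_NAMES[:4]
JITTER_FEATURES = FEATURE_NAMES[4:]

#: jitter_ppq5 needs a full 5-frame window, so shorter records are rejected
MIN_FRAMES = 5

META_COLUMNS = ("record_id", "subject_id", "label")


class RecordTooShortError(ValueError):
    pass


def ranges(xs, ys) -> tuple[float, float]:
    """(max - min) of each axis."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("empty trajectory")
    return float(xs.max() - xs.min()), float(ys.max() - ys.min())


def covariance(xs, ys) -> float:
    """Population covariance E(XY) - E(X)E(Y) (divide by N)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        raise ValueError("empty trajectory")
    return float(np.mean(xs * ys) - np.mean(xs) * np.mean(ys))


def euclid(p, q) -> float:
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def mean_position(P) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    return P.mean(axis=0)


def _traj(traj) -> np.ndarray:
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must have shape (n_frames, 2)")
    return traj


def jitter_abs(traj) -> float:
    """Mean Euclidean distance between adjacent frames; divisor N-1."""
    traj = _traj(traj)
    n = traj.shape[0]
    if n < 2:
        raise ValueError(f"jitter_abs needs >= 2 frames, got {n}")
    return float(np.mean(np.linalg.norm(np.diff(traj, axis=0), axis=1)))


def jitter_ppq5(traj) -> float:
    """Mean distance from each interior frame to its centered 5-frame mean.

    Windows are fully interior (frames 2 .. N-3, 0-based); divisor N-4.
    """
    traj = _traj(traj)
    n = traj.shape[0]
    if n < 5:
        raise ValueError(f"jitter_ppq5 needs >= 5 frames, got {n}")
    # deviation from the window mean written as a mean of pairwise
    # differences, so a constant trajectory gives exactly 0
    c = traj[2:-2]
    dev = ((c - traj[:-4]) + (c - traj[1:-3]) + (c - traj[3:-1]) + (c - traj[4:])) / 5.0
    return float(np.mean(np.linalg.norm(dev, axis=1)))


def jitter_rap(traj) -> float:
    """Mean distance from each interior frame to its centered 3-frame mean; divisor N-2."""
    traj = _traj(traj)
    n = traj.shape[0]
    if n < 3:
        raise ValueError(f"jitter_rap needs >= 3 frames, got {n}")
    c = traj[1:-1]
    dev = ((c - traj[:-2]) + (c - traj[2:])) / 3.0
    return float(np.mean(np.linalg.norm(dev, axis=1)))


def jitter_ddp(traj) -> float:
    """Mean |difference of consecutive adjacent-frame distances|; divisor N-2."""
    traj = _traj(traj)
    n = traj.shape[0]
    if n < 3:
        raise ValueError(f"jitter_ddp needs >= 3 frames, got {n}")
    d = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    return float(np.mean(np.abs(np.diff(d))))


@dataclass(frozen=True)
class KeypointFeatures:
    """The 8-feature block for one key point's trajectory."""

    R_x_max: float
    R_y_max: float
    cov_rel: float
    cov_abs: float
    jitter_abs: float
    jitter_ppq5: float
    jitter_rap: float
    jitter_ddp: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def keypoint_features(rel_traj, abs_traj) -> KeypointFeatures:
    """Compute all 8 features for one key point.

    ``rel_traj`` is the (N, 2) relative-coordinate trajectory (amplitude
    block), ``abs_traj`` the (N, 2) absolute-pixel trajectory (cov_abs
    and the jitter block).
    """
    rel_traj = _traj(rel_traj)
    abs_traj = _traj(abs_traj)
    if rel_traj.shape[0] != abs_traj.shape[0]:
        raise ValueError("relative and absolute trajectories are not aligned")
    if rel_traj.shape[0] < MIN_FRAMES:
        raise RecordTooShortError(
            f"record has {rel_traj.shape[0]} frames; minimum is {MIN_FRAMES}"
        )
    rx, ry = ranges(rel_traj[:, 0], rel_traj[:, 1])
    return KeypointFeatures(
        R_x_max=rx,
        R_y_max=ry,
        cov_rel=covariance(rel_traj[:, 0], rel_traj[:, 1]),
        cov_abs=covariance(abs_traj[:, 0], abs_traj[:, 1]),
        jitter_abs=jitter_abs(abs_traj),
        jitter_ppq5=jitter_ppq5(abs_traj),
        jitter_rap=jitter_rap(abs_traj),
        jitter_ddp=jitter_ddp(abs_traj),
    )


def feature_columns(schema) -> list[str]:
    """Canonical feature column order: points in schema order, 8 features each."""
    return [f"{p}__{f}" for p in schema.point_names for f in FEATURE_NAMES]


def extract_record(seq: LandmarkSequence, rel: RelativeSequence | None = None) -> pd.Series:
    """One record -> one row of the feature table (848 features + metadata).

    The relative conversion is computed on the fly (per-frame basis)
    when ``rel`` is not supplied.
    """
    if rel is None:
        rel = to_relative_sequence(seq)
    if rel.record_id != seq.record_id or rel.n_frames != seq.n_frames:
        raise ValueError("relative sequence does not match the record")
    if seq.n_frames < MIN_FRAMES:
        raise RecordTooShortError(
            f"record {seq.record_id!r} has {seq.n_frames} frames; "
            f"minimum is {MIN_FRAMES}"
        )
    abs_coords = seq.as_array()          # (N, P, 2)
    rel_coords = rel.coords

    values: dict[str, float] = {
        "record_id": seq.record_id,
        "subject_id": seq.subject_id,
        "label": seq.label,
    }
    # vectorized over points: each feature computed for all P trajectories at once
    rx = rel_coords[:, :, 0].max(axis=0) - rel_coords[:, :, 0].min(axis=0)
    ry = rel_coords[:, :, 1].max(axis=0) - rel_coords[:, :, 1].min(axis=0)

    def _cov(c):  # population covariance per point, c: (N, P, 2)
        x, y = c[:, :, 0], c[:, :, 1]
        return (x * y).mean(axis=0) - x.mean(axis=0) * y.mean(axis=0)

    cov_rel = _cov(rel_coords)
    cov_abs = _cov(abs_coords)

    step = np.linalg.norm(np.diff(abs_coords, axis=0), axis=2)       # (N-1, P)
    j_abs = step.mean(axis=0)
    c5 = abs_coords[2:-2]
    dev5 = ((c5 - abs_coords[:-4]) + (c5 - abs_coords[1:-3])
            + (c5 - abs_coords[3:-1]) + (c5 - abs_coords[4:])) / 5.0
    j_ppq5 = np.linalg.norm(dev5, axis=2).mean(axis=0)
    c3 = abs_coords[1:-1]
    dev3 = ((c3 - abs_coords[:-2]) + (c3 - abs_coords[2:])) / 3.0
    j_rap = np.linalg.norm(dev3, axis=2).mean(axis=0)
    j_ddp = np.abs(np.diff(step, axis=0)).mean(axis=0)

    blocks = (rx, ry, cov_rel, cov_abs, j_abs, j_ppq5, j_rap, j_ddp)
    for p_idx, point in enumerate(seq.schema.point_names):
        for f_idx, feat in enumerate(FEATURE_NAMES):
            values[f"{point}__{feat}"] = float(blocks[f_idx][p_idx])
    return pd.Series(values)


def build_feature_table(
    sequences,
    rels=None,
    basis_policy: str = "per_frame",
) -> pd.DataFrame:
    """Extract features for every record into a FeatureTable DataFrame.

    Columns: record_id, subject_id, label, then the 848 canonical
    feature columns in fixed order.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no records supplied")
    if rels is None:
        rels = [to_relative_sequence(s, basis_policy=basis_policy) for s in sequences]
    rows = [extract_record(s, r) for s, r in zip(sequences, rels)]
    table = pd.DataFrame(rows)
    ordered = list(META_COLUMNS) + feature_columns(sequences[0].schema)
    return table[ordered]


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Split a FeatureTable into (X, y, groups, feature_names).

    y is 1 for the PD class, 0 for control; groups are subject ids.
    """
    feats = [c for c in table.columns if c not in META_COLUMNS]
    X = table[feats].to_numpy(dtype=float)
    y = (table["label"] == "PD").to_numpy(dtype=int)
    groups = table["subject_id"].to_numpy()
    return X, y, groups, feats
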