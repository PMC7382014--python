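"""Landmark-sequence data model and I/O.

A record is a :class:`LandmarkSequence`: ordered frames of 106 absolute
pixel coordinates plus subject/record/label metadata. The canonical
on-disk form is a long-format CSV table (frame_index, point_name, m, n);
per-frame JSON detection results in the Face++-style dialect
(``{"landmark": {name: {"x": .., "y": ..}, ...}}``) are an import
dialect only.
"""

from __future__ import annotations

import glob as _glob
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, SchemaMap

LABEL_PD = "PD"
LABEL_CONTROL = "control"
VALID_LABELS = (LABEL_PD, LABEL_CONTROL)


class SchemaError(ValueError):
    """A frame's points do not match the landmark schema."""


class ManifestError(ValueError):
    """A dataset manifest row cannot be resolved into a valid record."""


@dataclass(frozen=True)
class LandmarkPoint:
    """One landmark in absolute image coordinates.

    ``m`` is the horizontal pixel coordinate, ``n`` the vertical pixel
    coordinate (origin at the image top-left, n increasing downward).
    """

    m: float
    n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m) and np.isfinite(self.n)):
            raise ValueError(f"non-finite landmark coordinates ({self.m}, {self.n})")


@dataclass(frozen=True)
class LandmarkFrame:
    """All landmark points of one video frame, in schema order."""

    index: int
    time_s: float
    points: tuple[LandmarkPoint, ...]

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    def as_array(self) -> np.ndarray:
        """(n_points, 2) float array of (m, n) coordinates."""
        return np.array([(p.m, p.n) for p in self.points], dtype=float)


@dataclass(frozen=True)
class LandmarkSequence:
    """One record: ordered landmark frames plus metadata."""

    subject_id: str
    record_id: str
    label: str
    frames: tuple[LandmarkFrame, ...]
    frame_interval_s: float = 0.1
    schema: SchemaMap = field(default=DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )
        if len(self.frames) < 1:
            raise ValueError("a sequence needs at least one frame")
        n = self.schema.n_points
        for i, fr in enumerate(self.frames):
            if fr.index != i:
                raise ValueError(
                    f"frame indices must be consecutive from 0; got {fr.index} at {i}"
                )
            if len(fr.points) != n:
                raise SchemaError(
                    f"frame {i} has {len(fr.points)} points, schema expects {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """(n_frames, n_points, 2) float array of absolute coordinates.

        The array is memoized and returned read-only.
        """
        cached = self.__dict__.get("_array")
        if cached is None:
            cached = np.stack([fr.as_array() for fr in self.frames])
            cached.flags.writeable = False
            object.__setattr__(self, "_array", cached)
        return cached


def frames_from_array(
    coords: np.ndarray, frame_interval_s: float = 0.1
) -> tuple[LandmarkFrame, ...]:
    """Build LandmarkFrame objects from a (n_frames, n_points, 2) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 2:
        raise ValueError("expected array of shape (n_frames, n_points, 2)")
    return tuple(
        LandmarkFrame(
            index=i,
            time_s=i * frame_interval_s,
            points=tuple(LandmarkPoint(m=float(m), n=float(n)) for m, n in frame),
        )
        for i, frame in enumerate(coords)
    )


def sequence_from_array(
    coords: np.ndarray,
    subject_id: str,
    record_id: str,
    label: str,
    frame_interval_s: float = 0.1,
    schema: SchemaMap = DEFAULT_SCHEMA,
) -> LandmarkSequence:
    """Convenience constructor from a (n_frames, n_points, 2) array."""
    return LandmarkSequence(
        subject_id=subject_id,
        record_id=record_id,
        label=label,
        frames=frames_from_array(coords, frame_interval_s),
        frame_interval_s=frame_interval_s,
        schema=schema,
    )


# ---------------------------------------------------------------------------
# Face++-dialect JSON import
# ---------------------------------------------------------------------------

def read_faceplusplus_json(
    path: str | Path, schema: SchemaMap = DEFAULT_SCHEMA
) -> tuple[LandmarkPoint, ...]:
    """Read one frame's landmarks from a Face++-dialect JSON file.

    The file must be a JSON object with a ``landmark`` mapping of point
    name -> ``{"x": .., "y": ..}`` (a bare mapping without the
    ``landmark`` wrapper is also accepted). Points are returned in
    schema order; any missing or extra names raise :class:`SchemaError`.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    landmark = payload.get("landmark", payload)
    if not isinstance(landmark, dict):
        raise SchemaError(f"{path}: 'landmark' is not a mapping")

    expected = set(schema.point_names)
    got = set(landmark)
    missing = sorted(expected - got)
    extra = sorted(got - expected)
    if missing or extra:
        raise SchemaError(
            f"{path}: expected {schema.n_points} landmark points; "
            f"missing={missing!r} extra={extra!r}"
        )
    points = []
    for name in schema.point_names:
        entry = landmark[name]
        try:
            points.append(LandmarkPoint(m=float(entry["x"]), n=float(entry["y"])))
        except (TypeError, KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: bad coordinates for {name!r}: {exc}") from exc
    return tuple(points)


# ---------------------------------------------------------------------------
# canonical landmark table (long CSV)
# ---------------------------------------------------------------------------

def write_landmark_table(seq: LandmarkSequence, path: str | Path) -> None:
    """Write a sequence as a long CSV: frame_index, point_name, m, n.

    Full float precision is kept so write/read round-trips are lossless.
    """
    names = seq.schema.point_names
    rows = {
        "frame_index": np.repeat(np.arange(seq.n_frames), len(names)),
        "point_name": list(names) * seq.n_frames,
        "m": seq.as_array()[:, :, 0].ravel(),
        "n": seq.as_array()[:, :, 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_landmark_table(
    path: str | Path,
    subject_id: str = "",
    record_id: str = "",
    label: str = LABEL_CONTROL,
    frame_interval_s: float = 0.1,
    schema: SchemaMap = DEFAULT_SCHEMA,
) -> LandmarkSequence:
    """Read a long-format landmark CSV back into a LandmarkSequence."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"frame_index", "point_name", "m", "n"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.duplicated(["frame_index", "point_name"]).any():
        dup = df[df.duplicated(["frame_index", "point_name"])].iloc[0]
        raise SchemaError(
            f"{path}: duplicate row for frame {dup['frame_index']}, "
            f"point {dup['point_name']!r}"
        )
    name_to_col = {name: i for i, name in enumerate(schema.point_names)}
    unknown = set(df["point_name"]) - set(name_to_col)
    if unknown:
        raise SchemaError(f"{path}: unknown point names {sorted(unknown)!r}")
    frame_ids = np.sort(df["frame_index"].unique())
    n_frames = len(frame_ids)
    if not np.array_equal(frame_ids, np.arange(n_frames)):
        raise SchemaError(f"{path}: frame indices must be consecutive from 0")
    coords = np.full((n_frames, schema.n_points, 2), np.nan)
    fi = df["frame_index"].to_numpy()
    pi = df["point_name"].map(name_to_col).to_numpy()
    coords[fi, pi, 0] = df["m"].to_numpy(dtype=float)
    coords[fi, pi, 1] = df["n"].to_numpy(dtype=float)
    if np.isnan(coords).any():
        bad = np.argwhere(np.isnan(coords[:, :, 0]))
        frame, point = bad[0]
        raise SchemaError(
            f"{path}: frame {frame} is missing point "
            f"{schema.point_names[point]!r} (and possibly others)"
        )
    return sequence_from_array(
        coords, subject_id, record_id, label, frame_interval_s, schema
    )


# ---------------------------------------------------------------------------
# manifest loading
# ---------------------------------------------------------------------------

def normalize_label(raw: str) -> str:
    """Map a raw manifest label to one of the two canonical classes."""
    cleaned = str(raw).strip()
    for label in VALID_LABELS:
        if cleaned.lower() == label.lower():
            return label
    raise ManifestError(f"unknown label {raw!r}; expected one of {VALID_LABELS}")


def load_dataset(
    manifest: str | Path, schema: SchemaMap = DEFAULT_SCHEMA
) -> list[LandmarkSequence]:
    """Load all records listed in a manifest CSV.

    Manifest columns: subject_id, record_id, label, frame_interval and
    ``path`` — either a landmark-table CSV or a glob of per-frame JSON
    files (sorted lexicographically to define frame order). Relative
    paths resolve against the manifest's directory.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    required = {"subject_id", "record_id", "label", "frame_interval", "path"}
    if not required.issubset(df.columns):
        raise ManifestError(
            f"{manifest}: missing columns {sorted(required - set(df.columns))}"
        )
    base = manifest.parent
    sequences: list[LandmarkSequence] = []
    for _, row in df.iterrows():
        record_id = str(row["record_id"])
        label = normalize_label(row["label"])
        interval = float(row["frame_interval"])
        raw_path = str(row["path"])
        target = Path(raw_path)
        if not target.is_absolute():
            target = base / target
        if target.suffix.lower() == ".csv" and target.exists():
            seq = read_landmark_table(
                target,
                subject_id=str(row["subject_id"]),
                record_id=record_id,
                label=label,
                frame_interval_s=interval,
                schema=schema,
            )
        else:
            frame_files = sorted(_glob.glob(str(target)))
            if not frame_files:
                raise ManifestError(
                    f"record {record_id!r}: no frames match {raw_path!r}"
                )
            frames = tuple(
                LandmarkFrame(
                    index=i,
                    time_s=i * interval,
                    points=read_faceplusplus_json(f, schema),
                )
                for i, f in enumerate(frame_files)
            )
            seq = LandmarkSequence(
                subject_id=str(row["subject_id"]),
                record_id=record_id,
                label=label,
                frames=frames,
                frame_interval_s=interval,
                schema=schema,
            )
        sequences.append(seq)
    return sequences


def write_manifest(
    rows: Iterable[dict], path: str | Path
) -> None:
    """Write a manifest CSV from dicts with the canonical columns."""
    df = pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def save_cohort(
    sequences: Sequence[LandmarkSequence], out_dir: str | Path
) -> Path:
    """Write each sequence as a landmark table plus a manifest; return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in sequences:
        fname = f"{seq.record_id}.csv"
        write_landmark_table(seq, out_dir / fname)
        rows.append(
            {
                "subject_id": seq.subject_id,
                "record_id": seq.record_id,
                "label": seq.label,
                "frame_interval": seq.frame_interval_s,
                "path": fname,
            }
        )
    manifest_path = out_dir / "manifest.csv"
    write_manifest(rows, manifest_path)
    return manifest_path
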