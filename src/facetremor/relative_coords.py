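"""Face-anchored relative coordinate system.

Absolute pixel coordinates are re-expressed in a non-Cartesian frame
anchored to the face: origin at the midpoint of the inner eye corners,
basis vector ``a`` pointing to the right inner eye corner and basis
vector ``b`` pointing from the nose anchor up to the origin. In that
frame the right inner eye corner sits at (1, 0), the left at (-1, 0)
and the nose anchor at (0, -1), regardless of head translation,
rotation or uniform scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkFrame, LandmarkSequence
from .schema import DEFAULT_SCHEMA, SchemaMap

#: |det| below this fraction of ||a||*||b|| means the anchors are
#: (nearly) collinear and the basis is unusable. Scale-free on purpose.
DEGENERACY_RTOL = 1e-6


class DegenerateFaceError(ValueError):
    """Anchor points are collinear; no 2-D basis can be formed."""


@dataclass(frozen=True)
class FaceBasis:
    """Affine basis of the face-anchored coordinate frame for one frame."""

    origin: np.ndarray  # midpoint of inner eye corners, absolute pixels
    a: np.ndarray       # right inner eye corner - origin
    b: np.ndarray       # origin - nose anchor

    @property
    def det(self) -> float:
        return float(self.a[0] * self.b[1] - self.a[1] * self.b[0])

    def __post_init__(self) -> None:
        scale = float(np.linalg.norm(self.a) * np.linalg.norm(self.b))
        if abs(self.det) <= DEGENERACY_RTOL * scale or scale == 0.0:
            raise DegenerateFaceError(
                f"anchors are collinear (det={self.det:.3e}, scale={scale:.3e})"
            )


def face_basis(
    frame: LandmarkFrame | np.ndarray, schema: SchemaMap = DEFAULT_SCHEMA
) -> FaceBasis:
    """Build the face basis from one frame's anchor points.

    Accepts a LandmarkFrame or a raw (n_points, 2) coordinate array.
    """
    coords = frame.as_array() if isinstance(frame, LandmarkFrame) else np.asarray(frame, dtype=float)
    li, ri, ni = schema.anchor_indices
    left, right, nose = coords[li], coords[ri], coords[ni]
    origin = (left + right) / 2.0
    return FaceBasis(origin=origin, a=right - origin, b=origin - nose)


def to_relative(p, basis: FaceBasis) -> np.ndarray:
    """Map absolute point(s) into the face frame: solve p - origin = x*a + y*b.

    ``p`` may be a single (2,) point or an (..., 2) array; the result has
    the same shape.
    """
    p = np.asarray(p, dtype=float)
    rhs = p - basis.origin
    # explicit 2x2 inverse (Cramer); exact up to float rounding
    det = basis.det
    x = (rhs[..., 0] * basis.b[1] - rhs[..., 1] * basis.b[0]) / det
    y = (basis.a[0] * rhs[..., 1] - basis.a[1] * rhs[..., 0]) / det
    return np.stack([x, y], axis=-1)


def from_relative(rel, basis: FaceBasis) -> np.ndarray:
    """Inverse map: x*a + y*b + origin."""
    rel = np.asarray(rel, dtype=float)
    return rel[..., :1] * basis.a + rel[..., 1:] * basis.b + basis.origin


@dataclass(frozen=True)
class RelativeSequence:
    """A record's frames expressed in the face-anchored frame.

    Keeps the same metadata as the source LandmarkSequence plus the
    per-frame basis used for the conversion.
    """

    subject_id: str
    record_id: str
    label: str
    coords: np.ndarray                 # (n_frames, n_points, 2) relative
    bases: tuple[FaceBasis, ...]       # one per frame (repeated for first_frame policy)
    frame_interval_s: float = 0.1
    schema: SchemaMap = field(default=DEFAULT_SCHEMA)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])


def to_relative_sequence(
    seq: LandmarkSequence,
    schema: SchemaMap | None = None,
    basis_policy: str = "per_frame",
) -> RelativeSequence:
    """Convert a whole record to relative coordinates.

    basis_policy:
      ``per_frame`` (default) recomputes the anchor basis on every frame,
      cancelling rigid head motion within the record; ``first_frame``
      reuses frame 0's basis throughout (kept for ablation).
    """
    if basis_policy not in ("per_frame", "first_frame"):
        raise ValueError(f"unknown basis_policy {basis_policy!r}")
    schema = schema or seq.schema
    abs_coords = seq.as_array()
    bases: list[FaceBasis] = []
    rel = np.empty_like(abs_coords)
    first: FaceBasis | None = None
    for i in range(abs_coords.shape[0]):
        try:
            if basis_policy == "per_frame" or first is None:
                basis = face_basis(abs_coords[i], schema)
                if first is None:
                    first = basis
            if basis_policy == "first_frame":
                basis = first
        except DegenerateFaceError as exc:
            raise DegenerateFaceError(f"frame {i}: {exc}") from exc
        bases.append(basis)
        rel[i] = to_relative(abs_coords[i], basis)
    return RelativeSequence(
        subject_id=seq.subject_id,
        record_id=seq.record_id,
        label=seq.label,
        coords=rel,
        bases=tuple(bases),
        frame_interval_s=seq.frame_interval_s,
        schema=schema,
    )
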