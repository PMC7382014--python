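"""106-point facial landmark schema.

The point layout mirrors the usual commercial 106-point convention:
33 facial-contour points, 9 points per eyebrow, 10 points per eye,
15 nose points and 20 mouth points. Point *names* are what the rest of
the package keys on; vendor index numbering is deliberately not used so
the math is decoupled from any particular provider.

Three points act as anchors for the face-anchored coordinate system:
the two inner eye corners and a nose anchor (default: the nose tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_point_names() -> tuple[str, ...]:
    names: list[str] = []
    # facial contour: chin apex plus 16 points up each side
    names.append("contour_chin")
    names += [f"contour_left_{i}" for i in range(1, 17)]
    names += [f"contour_right_{i}" for i in range(1, 17)]
    # eyebrows
    names += [f"left_eyebrow_{i}" for i in range(1, 10)]
    names += [f"right_eyebrow_{i}" for i in range(1, 10)]
    # eyes: 9 rim points plus the inner corner, per side
    names += [f"left_eye_{i}" for i in range(1, 10)]
    names.append("left_eye_inner_corner")
    names += [f"right_eye_{i}" for i in range(1, 10)]
    names.append("right_eye_inner_corner")
    # nose: tip, bridge, side contours, columella base
    names.append("nose_tip")
    names += [f"nose_bridge_{i}" for i in range(1, 4)]
    names += [f"nose_left_contour_{i}" for i in range(1, 6)]
    names += [f"nose_right_contour_{i}" for i in range(1, 6)]
    names.append("nose_base")
    # mouth
    names += [f"mouth_{i}" for i in range(1, 21)]
    assert len(names) == 106
    return tuple(names)


DEFAULT_POINT_NAMES: tuple[str, ...] = _default_point_names()

N_POINTS = 106


@dataclass(frozen=True)
class SchemaMap:
    """Names of the 106 landmark points plus the three designated anchors.

    Parameters
    ----------
    point_names
        Ordered names of all landmark points (exactly 106 by default).
    left_inner_eye_corner, right_inner_eye_corner, nose_anchor
        Names of the anchor points used to build the face-anchored
        coordinate basis. All three must resolve to distinct points.
    """

    point_names: tuple[str, ...] = field(default=DEFAULT_POINT_NAMES)
    left_inner_eye_corner: str = "left_eye_inner_corner"
    right_inner_eye_corner: str = "right_eye_inner_corner"
    nose_anchor: str = "nose_tip"

    def __post_init__(self) -> None:
        if len(set(self.point_names)) != len(self.point_names):
            raise ValueError("duplicate point names in schema")
        anchors = (
            self.left_inner_eye_corner,
            self.right_inner_eye_corner,
            self.nose_anchor,
        )
        for a in anchors:
            if a not in self.point_names:
                raise ValueError(f"anchor {a!r} not among schema point names")
        idx = {self.index_of(a) for a in anchors}
        if len(idx) != 3:
            raise ValueError("anchor names must resolve to three distinct points")

    @property
    def n_points(self) -> int:
        return len(self.point_names)

    def index_of(self, name: str) -> int:
        try:
            return self.point_names.index(name)
        except ValueError:
            raise KeyError(f"point name {name!r} not in schema") from None

    @property
    def anchor_indices(self) -> tuple[int, int, int]:
        """(left inner eye corner, right inner eye corner, nose anchor)."""
        return (
            self.index_of(self.left_inner_eye_corner),
            self.index_of(self.right_inner_eye_corner),
            self.index_of(self.nose_anchor),
        )


DEFAULT_SCHEMA = SchemaMap()
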