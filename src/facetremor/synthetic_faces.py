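"""Synthetic landmark-sequence cohorts.

Generates two-group cohorts with the statistical structure the analysis
pipeline assumes: per-subject repeated records of a smooth smile whose
amplitude depends on group, per-frame isotropic positional noise
("tremor") whose scale depends on group, and optional nuisance rigid
head motion. Realism is a non-goal; the statistical structure is the
goal.

Tremor is modeled as white positional noise rather than an explicit
4-6 Hz oscillation: at a 10 Hz frame rate physiological tremor sits at
or above the Nyquist frequency, so a sinusoid model would be aliased
anyway, and white noise is exactly what the positional-jitter statistics
measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import LABEL_CONTROL, LABEL_PD, LandmarkSequence, sequence_from_array
from .schema import DEFAULT_SCHEMA, SchemaMap

#: template geometry constants (pixels; image origin top-left, y down)
_FACE_CENTER = np.array([320.0, 240.0])
_EYE_HALF_DIST = 60.0
_EYE_Y = 200.0
_MOUTH_CENTER = np.array([320.0, 330.0])


def default_signal_points() -> tuple[str, ...]:
    """Mouth plus outer-eye-corner region: where expression signal lives."""
    return tuple(
        [f"mouth_{i}" for i in range(1, 21)]
        + ["left_eye_1", "left_eye_2", "right_eye_1", "right_eye_2"]
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort parameters; all randomness derives from ``seed``."""

    n_pd: int = 30
    n_ctrl: int = 30
    records_per_subject: int = 3
    frames_per_record: int = 50
    frame_interval_s: float = 0.1
    smile_amplitude_pd: float = 0.08     # relative units (eye-half-distances)
    smile_amplitude_ctrl: float = 0.25
    tremor_sigma_pd: float = 1.2         # pixels per frame per axis
    tremor_sigma_ctrl: float = 0.3
    head_motion: str = "none"            # none | drift | rotation
    head_motion_magnitude: float = 0.0   # px/frame (drift) or total degrees (rotation)
    signal_points: tuple[str, ...] = field(default_factory=default_signal_points)
    seed: int = 0
    schema: SchemaMap = field(default=DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if self.n_pd < 1 or self.n_ctrl < 1 or self.records_per_subject < 1:
            raise ValueError("subject and record counts must be >= 1")
        if self.frames_per_record < 1:
            raise ValueError("frames_per_record must be >= 1")
        if min(self.smile_amplitude_pd, self.smile_amplitude_ctrl) < 0:
            raise ValueError("smile amplitudes must be >= 0")
        if min(self.tremor_sigma_pd, self.tremor_sigma_ctrl) < 0:
            raise ValueError("tremor sigmas must be >= 0")
        if self.head_motion not in ("none", "drift", "rotation"):
            raise ValueError(f"unknown head_motion {self.head_motion!r}")
        unknown = set(self.signal_points) - set(self.schema.point_names)
        if unknown:
            raise ValueError(f"signal points not in schema: {sorted(unknown)}")


def template_face(schema: SchemaMap = DEFAULT_SCHEMA) -> np.ndarray:
    """Neutral-face template: (n_points, 2) absolute pixel coordinates.

    A stylized frontal layout; the three anchors sit at canonical spots
    (inner eye corners level and symmetric, nose tip on the midline).
    """
    cx, cy = _FACE_CENTER
    pos: dict[str, np.ndarray] = {}

    # facial contour: lower half-ellipse, chin at the bottom apex
    pos["contour_chin"] = np.array([cx, cy + 180.0])
    for i in range(1, 17):
        ang = np.pi / 2 + (np.pi * 0.9) * i / 17.0
        pos[f"contour_left_{i}"] = np.array(
            [cx + 140.0 * np.cos(ang), cy + 180.0 * np.sin(ang)]
        )
        pos[f"contour_right_{i}"] = np.array(
            [cx - 140.0 * np.cos(ang), cy + 180.0 * np.sin(ang)]
        )

    # eyebrows: arcs above each eye
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        for i in range(1, 10):
            frac = (i - 1) / 8.0
            pos[f"{side}_eyebrow_{i}"] = np.array(
                [
                    cx + sgn * (30.0 + 70.0 * frac),
                    _EYE_Y - 40.0 - 12.0 * np.sin(np.pi * frac),
                ]
            )

    # eyes: inner corner pinned at +-eye-half-distance, 9 rim points around
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        inner = np.array([cx + sgn * _EYE_HALF_DIST, _EYE_Y])
        pos[f"{side}_eye_inner_corner"] = inner
        center = inner + np.array([sgn * 25.0, 0.0])
        for i in range(1, 10):
            ang = 2 * np.pi * (i - 1) / 9.0
            pos[f"{side}_eye_{i}"] = center + np.array(
                [22.0 * np.cos(ang), 9.0 * np.sin(ang)]
            )

    # nose
    pos["nose_tip"] = np.array([cx, _EYE_Y + 60.0])
    for i in range(1, 4):
        pos[f"nose_bridge_{i}"] = np.array([cx, _EYE_Y + 12.0 * i])
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        for i in range(1, 6):
            pos[f"nose_{side}_contour_{i}"] = np.array(
                [cx + sgn * (8.0 + 4.0 * i), _EYE_Y + 25.0 + 8.0 * i]
            )
    pos["nose_base"] = np.array([cx, _EYE_Y + 72.0])

    # mouth: ellipse of 20 points
    for i in range(1, 21):
        ang = 2 * np.pi * (i - 1) / 20.0
        pos[f"mouth_{i}"] = _MOUTH_CENTER + np.array(
            [50.0 * np.cos(ang), 20.0 * np.sin(ang)]
        )

    return np.stack([pos[name] for name in schema.point_names])


def _smile_direction_field(schema: SchemaMap, signal_idx: np.ndarray) -> np.ndarray:
    """Unit-amplitude displacement direction per signal point (pixels).

    Points spread laterally away from the midline and rise (negative
    image-y); lateral spread grows with distance from the mouth center,
    mimicking mouth corners pulling out and up in a smile.
    """
    template = template_face(schema)
    cx = _FACE_CENTER[0]
    directions = np.zeros((len(signal_idx), 2))
    for k, idx in enumerate(signal_idx):
        px = template[idx, 0]
        lateral = np.clip((px - cx) / 60.0, -1.0, 1.0)
        directions[k] = (0.6 * lateral, -1.0)
    return directions


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def generate_cohort(cfg: SyntheticConfig) -> list[LandmarkSequence]:
    """Generate all records of the configured cohort, reproducibly from the seed."""
    rng = np.random.default_rng(cfg.seed)
    schema = cfg.schema
    template = template_face(schema)
    signal_idx = np.array([schema.index_of(p) for p in cfg.signal_points], dtype=int)
    directions = _smile_direction_field(schema, signal_idx)
    n_frames = cfg.frames_per_record
    t = np.arange(n_frames, dtype=float)
    smile_profile = np.sin(np.pi * t / max(n_frames - 1, 1))  # neutral-peak-neutral

    sequences: list[LandmarkSequence] = []
    groups = [(LABEL_PD, "pd", cfg.n_pd, cfg.smile_amplitude_pd, cfg.tremor_sigma_pd),
              (LABEL_CONTROL, "ctrl", cfg.n_ctrl, cfg.smile_amplitude_ctrl, cfg.tremor_sigma_ctrl)]
    for label, prefix, n_subjects, amplitude, sigma in groups:
        for s in range(n_subjects):
            subject_id = f"{prefix}_{s:03d}"
            # subject-level idiosyncrasy: mild scale + placement offset
            subj_scale = rng.uniform(0.95, 1.05)
            subj_offset = rng.uniform(-15.0, 15.0, size=2)
            subj_face = (template - _FACE_CENTER) * subj_scale + _FACE_CENTER + subj_offset
            for r in range(cfg.records_per_subject):
                record_id = f"{subject_id}_r{r}"
                rec_amp = amplitude * rng.uniform(0.9, 1.1)
                amp_px = rec_amp * _EYE_HALF_DIST * subj_scale
                coords = np.repeat(subj_face[None, :, :], n_frames, axis=0)
                # smooth smile displacement on signal points
                disp = (
                    smile_profile[:, None, None]
                    * amp_px
                    * directions[None, :, :]
                )
                coords[:, signal_idx, :] = coords[:, signal_idx, :] + disp
                # nuisance rigid head motion applied to every point
                if cfg.head_motion == "drift" and cfg.head_motion_magnitude > 0:
                    heading = rng.uniform(0, 2 * np.pi)
                    vel = cfg.head_motion_magnitude * np.array(
                        [np.cos(heading), np.sin(heading)]
                    )
                    coords += (t[:, None] * vel)[:, None, :]
                elif cfg.head_motion == "rotation" and cfg.head_motion_magnitude > 0:
                    total = np.deg2rad(cfg.head_motion_magnitude)
                    for i in range(n_frames):
                        R = _rotation(total * i / max(n_frames - 1, 1))
                        coords[i] = coords[i] @ R.T
                # white positional tremor noise on every point
                if sigma > 0:
                    coords += rng.normal(0.0, sigma, size=coords.shape)
                sequences.append(
                    sequence_from_array(
                        coords,
                        subject_id=subject_id,
                        record_id=record_id,
                        label=label,
                        frame_interval_s=cfg.frame_interval_s,
                        schema=schema,
                    )
                )
    return sequences


def effect_audit(
    cohort: list[LandmarkSequence], cfg: SyntheticConfig
) -> pd.DataFrame:
    """Per-group mean jitter_abs and mean R_y_max over the signal points.

    A quick check that the generator actually realizes its configured
    amplitude and tremor effects.
    """
    from .relative_coords import to_relative_sequence
    from .trajectory_features import jitter_abs as _jabs

    signal_idx = np.array(
        [cfg.schema.index_of(p) for p in cfg.signal_points], dtype=int
    )
    rows = []
    for seq in cohort:
        abs_coords = seq.as_array()[:, signal_idx, :]
        jit = (
            float(
                np.mean([_jabs(abs_coords[:, k]) for k in range(len(signal_idx))])
            )
            if seq.n_frames >= 2
            else 0.0
        )
        rel = to_relative_sequence(seq).coords[:, signal_idx, :]
        ry = float(np.mean(rel[:, :, 1].max(axis=0) - rel[:, :, 1].min(axis=0)))
        rows.append({"label": seq.label, "jitter_abs": jit, "R_y_max": ry})
    df = pd.DataFrame(rows)
    return df.groupby("label")[["jitter_abs", "R_y_max"]].mean()
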