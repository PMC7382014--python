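import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facetremor.landmark_io import sequence_from_array
from facetremor.relative_coords import to_relative_sequence
from facetremor.schema import DEFAULT_SCHEMA
from facetremor.trajectory_features import (
    FEATURE_NAMES,
    RecordTooShortError,
    build_feature_table,
    covariance,
    euclid,
    extract_record,
    feature_columns,
    jitter_abs,
    jitter_ddp,
    jitter_ppq5,
    jitter_rap,
    keypoint_features,
    mean_position,
    ranges,
)

from conftest import random_frame


# ---------------------------------------------------------------------------
# independent brute-force oracles (naive double loops, no numpy vectorization)
# ---------------------------------------------------------------------------

def _dist(p, q):
    return math.hypot(p[0] - q[0], p[1] - q[1])


def brute_jitter_abs(traj):
    n = len(traj)
    return sum(_dist(traj[i], traj[i + 1]) for i in range(n - 1)) / (n - 1)


def brute_window_jitter(traj, half):
    n = len(traj)
    total = 0.0
    count = 0
    for i in range(half, n - half):
        window = traj[i - half : i + half + 1]
        mx = sum(p[0] for p in window) / len(window)
        my = sum(p[1] for p in window) / len(window)
        total += _dist(traj[i], (mx, my))
        count += 1
    return total / count


def brute_jitter_ddp(traj):
    n = len(traj)
    total = 0.0
    for i in range(1, n - 1):
        total += abs(_dist(traj[i], traj[i + 1]) - _dist(traj[i - 1], traj[i]))
    return total / (n - 2)


class TestElementaryOps:
    def test_ranges(self):
        assert ranges([0.1, 0.5, 0.3], [0, 0, 0])[0] == pytest.approx(0.4)
        assert ranges([1, 1, 1], [2, 2, 2]) == (0.0, 0.0)
        assert ranges([-1, 1], [2, -2]) == (2.0, 4.0)

    def test_ranges_empty_rejected(self):
        with pytest.raises(ValueError):
            ranges([], [])

    def test_covariance_hand_computed(self):
        assert covariance([1, 2, 3], [2, 4, 6]) == pytest.approx(4 / 3)
        assert covariance([1, 2, 3], [5, 5, 5]) == pytest.approx(0.0)
        assert covariance([0, 1], [0, 1]) == pytest.approx(0.25)

    def test_covariance_is_population_convention(self, rng):
        xs, ys = rng.normal(size=20), rng.normal(size=20)
        assert covariance(xs, ys) == pytest.approx(float(np.cov(xs, ys, bias=True)[0, 1]))

    def test_euclid(self):
        assert euclid((0, 0), (3, 4)) == pytest.approx(5.0)
        assert euclid((2, 7), (2, 7)) == 0.0
        assert euclid((1, 1), (4, 5)) == pytest.approx(5.0)

    def test_mean_position(self):
        np.testing.assert_allclose(mean_position([(0, 0), (2, 4)]), [1, 2])
        np.testing.assert_allclose(mean_position([(3, -1)]), [3, -1])
        np.testing.assert_allclose(mean_position([(1, 0), (0, 1), (-1, -1)]), [0, 0])


class TestJitterExamples:
    def test_jitter_abs_hand_computed(self):
        assert jitter_abs([(0, 0), (3, 4), (3, 4)]) == pytest.approx(2.5)
        assert jitter_abs([(1, 1)] * 6) == 0.0
        assert jitter_abs([(0, 0), (1, 0), (2, 0)]) == pytest.approx(1.0)

    def test_jitter_abs_needs_two_frames(self):
        with pytest.raises(ValueError):
            jitter_abs([(0, 0)])

    def test_jitter_ppq5_hand_computed(self):
        assert jitter_ppq5([(2, 2)] * 5) == 0.0
        assert jitter_ppq5([(0, 0), (0, 0), (5, 0), (0, 0), (0, 0)]) == pytest.approx(4.0)
        # uniform linear motion: centered 5-mean equals the center point
        linear = [(2.0 * i, -1.0 * i) for i in range(9)]
        assert jitter_ppq5(linear) == pytest.approx(0.0, abs=1e-12)

    def test_jitter_ppq5_needs_five_frames(self):
        with pytest.raises(ValueError):
            jitter_ppq5([(0, 0)] * 4)

    def test_jitter_rap_hand_computed(self):
        assert jitter_rap([(5, 5)] * 4) == 0.0
        assert jitter_rap([(0, 0), (3, 0), (0, 0)]) == pytest.approx(2.0)
        linear = [(1.5 * i, 0.5 * i) for i in range(7)]
        assert jitter_rap(linear) == pytest.approx(0.0, abs=1e-12)

    def test_jitter_ddp_hand_computed(self):
        assert jitter_ddp([(0, 0), (1, 0), (3, 0), (6, 0)]) == pytest.approx(1.0)
        assert jitter_ddp([(0, 0), (2, 0), (4, 0), (6, 0)]) == 0.0
        assert jitter_ddp([(0, 0), (0, 3), (0, 3)]) == pytest.approx(3.0)


class TestJitterProperties:
    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=5, max_value=50))
    def test_brute_force_oracle_equivalence(self, seed, n):
        rng = np.random.default_rng(seed)
        traj = rng.uniform(-100, 100, size=(n, 2))
        traj_list = [tuple(p) for p in traj]
        assert jitter_abs(traj) == pytest.approx(brute_jitter_abs(traj_list), abs=1e-12)
        assert jitter_ppq5(traj) == pytest.approx(
            brute_window_jitter(traj_list, 2), abs=1e-12)
        assert jitter_rap(traj) == pytest.approx(
            brute_window_jitter(traj_list, 1), abs=1e-12)
        assert jitter_ddp(traj) == pytest.approx(brute_jitter_ddp(traj_list), abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_affine_in_time_has_zero_rap_and_ppq5(self, seed):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(-50, 50, size=2)
        v = rng.uniform(-5, 5, size=2)
        n = rng.integers(5, 30)
        traj = p0 + np.arange(n)[:, None] * v
        assert jitter_rap(traj) == pytest.approx(0.0, abs=1e-9)
        assert jitter_ppq5(traj) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000),
           st.floats(min_value=0.1, max_value=100.0))
    def test_scale_equivariance(self, seed, s):
        rng = np.random.default_rng(seed)
        traj = rng.uniform(-10, 10, size=(12, 2))
        for fn in (jitter_abs, jitter_ppq5, jitter_rap, jitter_ddp):
            assert fn(s * traj) == pytest.approx(s * fn(traj), rel=1e-9)
        assert covariance(s * traj[:, 0], s * traj[:, 1]) == pytest.approx(
            s**2 * covariance(traj[:, 0], traj[:, 1]), rel=1e-9)

    def test_noise_monotonicity_of_expected_jitter_abs(self):
        base = np.zeros((40, 2))
        means = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                vals.append(jitter_abs(base + rng.normal(0, sigma, size=base.shape)))
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestExtractRecord:
    def test_848_features_per_record(self, small_cohort):
        row = extract_record(small_cohort[0])
        feature_vals = [k for k in row.index if "__" in k]
        assert len(feature_vals) == 848

    def test_column_order_is_canonical(self, small_cohort):
        table = build_feature_table(small_cohort[:2])
        assert list(table.columns[3:]) == feature_columns(DEFAULT_SCHEMA)
        assert table.shape[1] == 848 + 3

    def test_static_record_all_zero(self):
        coords = np.repeat(random_frame(np.random.default_rng(1))[None], 6, axis=0)
        seq = sequence_from_array(coords, "s", "r", "PD")
        row = extract_record(seq)
        for feat in FEATURE_NAMES:
            vals = row[[k for k in row.index if k.endswith(f"__{feat}")]]
            np.testing.assert_allclose(vals.to_numpy(dtype=float), 0.0, atol=1e-12)

    def test_rigid_translation_zero_amplitude_positive_jitter(self, rng):
        frame0 = random_frame(rng)
        steps = np.cumsum(rng.uniform(0.5, 2.0, size=(8, 2)), axis=0)
        coords = frame0[None] + np.concatenate([np.zeros((1, 2)), steps])[:, None, :]
        seq = sequence_from_array(coords, "s", "r", "PD")
        row = extract_record(seq)
        rx = row[[k for k in row.index if k.endswith("__R_x_max")]].to_numpy(dtype=float)
        jab = row[[k for k in row.index if k.endswith("__jitter_abs")]].to_numpy(dtype=float)
        np.testing.assert_allclose(rx, 0.0, atol=1e-9)
        assert (jab > 0.1).all()

    def test_short_record_rejected(self, rng):
        coords = np.repeat(random_frame(rng)[None], 4, axis=0)
        seq = sequence_from_array(coords, "s", "r", "PD")
        with pytest.raises(RecordTooShortError):
            extract_record(seq)

    def test_extract_matches_scalar_keypoint_features(self, small_cohort):
        """Vectorized table row agrees with the per-point scalar path."""
        seq = small_cohort[0]
        rel = to_relative_sequence(seq)
        row = extract_record(seq, rel)
        abs_coords = seq.as_array()
        for p_idx in (0, 37, 105):
            name = DEFAULT_SCHEMA.point_names[p_idx]
            kf = keypoint_features(rel.coords[:, p_idx], abs_coords[:, p_idx])
            for feat, val in zip(FEATURE_NAMES, kf.as_tuple()):
                assert row[f"{name}__{feat}"] == pytest.approx(val, rel=1e-9, abs=1e-12)
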