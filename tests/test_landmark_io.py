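import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from facetremor.landmark_io import (
    LandmarkFrame,
    LandmarkPoint,
    LandmarkSequence,
    ManifestError,
    SchemaError,
    load_dataset,
    normalize_label,
    read_faceplusplus_json,
    read_landmark_table,
    save_cohort,
    sequence_from_array,
    write_landmark_table,
    write_manifest,
)
from facetremor.schema import DEFAULT_SCHEMA, SchemaMap


def _json_fixture(path, coords, schema=DEFAULT_SCHEMA, drop=(), extra=None):
    landmark = {
        name: {"x": float(m), "y": float(n)}
        for name, (m, n) in zip(schema.point_names, coords)
        if name not in drop
    }
    if extra:
        landmark.update(extra)
    path.write_text(json.dumps({"landmark": landmark}))
    return path


class TestSchemaMap:
    def test_default_has_106_points(self):
        assert DEFAULT_SCHEMA.n_points == 106

    def test_anchor_indices_distinct(self):
        assert len(set(DEFAULT_SCHEMA.anchor_indices)) == 3

    def test_bad_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            SchemaMap(nose_anchor="not_a_point")

    def test_duplicate_names_rejected(self):
        names = ("a",) * 3
        with pytest.raises(ValueError, match="duplicate"):
            SchemaMap(point_names=names, left_inner_eye_corner="a",
                      right_inner_eye_corner="a", nose_anchor="a")


class TestFaceppJson:
    def test_full_fixture_returns_106_points_in_order(self, tmp_path, rng):
        coords = rng.uniform(0, 500, size=(106, 2))
        path = _json_fixture(tmp_path / "f.json", coords)
        points = read_faceplusplus_json(path)
        assert len(points) == 106
        got = np.array([(p.m, p.n) for p in points])
        np.testing.assert_array_equal(got, coords)

    def test_missing_key_named_in_error(self, tmp_path, rng):
        coords = rng.uniform(0, 500, size=(106, 2))
        path = _json_fixture(tmp_path / "f.json", coords, drop=("nose_tip",))
        with pytest.raises(SchemaError, match="nose_tip"):
            read_faceplusplus_json(path)

    def test_empty_object_reports_all_106_missing(self, tmp_path):
        path = tmp_path / "f.json"
        path.write_text("{}")
        with pytest.raises(SchemaError) as err:
            read_faceplusplus_json(path)
        # all 106 names should be listed as missing
        assert all(n in str(err.value) for n in DEFAULT_SCHEMA.point_names)

    def test_extra_key_rejected(self, tmp_path, rng):
        coords = rng.uniform(0, 500, size=(106, 2))
        path = _json_fixture(tmp_path / "f.json", coords,
                             drop=("mouth_1",), extra={"bogus": {"x": 1, "y": 2}})
        with pytest.raises(SchemaError, match="bogus"):
            read_faceplusplus_json(path)

    def test_malformed_json(self, tmp_path):
        path = tmp_path / "f.json"
        path.write_text("{not json")
        with pytest.raises(SchemaError, match="malformed"):
            read_faceplusplus_json(path)


class TestSequenceInvariants:
    def test_nonfinite_point_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            LandmarkPoint(m=float("nan"), n=0.0)

    def test_wrong_point_count_rejected(self, rng):
        frame = LandmarkFrame(index=0, time_s=0.0,
                              points=(LandmarkPoint(0.0, 0.0),) * 10)
        with pytest.raises(SchemaError, match="10 points"):
            LandmarkSequence("s", "r", "PD", frames=(frame,))

    def test_nonconsecutive_frames_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(2, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "PD")
        with pytest.raises(ValueError, match="consecutive"):
            LandmarkSequence("s", "r", "PD", frames=(seq.frames[1],))

    def test_unknown_label_rejected(self, rng):
        coords = rng.uniform(0, 100, size=(1, 106, 2))
        with pytest.raises(ValueError, match="label"):
            sequence_from_array(coords, "s", "r", "sick")

    def test_as_array_shape(self, rng):
        coords = rng.uniform(0, 100, size=(4, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "control")
        assert seq.as_array().shape == (4, 106, 2)
        np.testing.assert_array_equal(seq.as_array(), coords)


class TestLandmarkTable:
    def test_round_trip_identity(self, tmp_path, rng):
        coords = rng.uniform(0, 640, size=(7, 106, 2))
        seq = sequence_from_array(coords, "s1", "r1", "PD")
        write_landmark_table(seq, tmp_path / "t.csv")
        back = read_landmark_table(tmp_path / "t.csv", "s1", "r1", "PD")
        np.testing.assert_array_equal(back.as_array(), seq.as_array())

    @settings(max_examples=20, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(n_frames=st.integers(min_value=1, max_value=4),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_property(self, n_frames, seed, tmp_path):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-1e6, 1e6, size=(n_frames, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "control")
        path = tmp_path / f"t{seed}_{n_frames}.csv"
        write_landmark_table(seq, path)
        back = read_landmark_table(path, "s", "r", "control")
        np.testing.assert_array_equal(back.as_array(), seq.as_array())

    def test_one_frame_gives_106_rows(self, tmp_path, rng):
        coords = rng.uniform(0, 100, size=(1, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "PD")
        write_landmark_table(seq, tmp_path / "t.csv")
        assert len(pd.read_csv(tmp_path / "t.csv")) == 106

    def test_duplicate_row_rejected(self, tmp_path, rng):
        coords = rng.uniform(0, 100, size=(1, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "PD")
        write_landmark_table(seq, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        pd.concat([df, df.iloc[[0]]]).to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(SchemaError, match="duplicate"):
            read_landmark_table(tmp_path / "dup.csv")

    def test_missing_point_rejected_no_partial_sequence(self, tmp_path, rng):
        coords = rng.uniform(0, 100, size=(2, 106, 2))
        seq = sequence_from_array(coords, "s", "r", "PD")
        write_landmark_table(seq, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        df.drop(index=[5]).to_csv(tmp_path / "part.csv", index=False)
        with pytest.raises(SchemaError, match="missing"):
            read_landmark_table(tmp_path / "part.csv")


class TestManifest:
    def _write_cohort(self, tmp_path, rng, n_frames=50):
        seqs = [
            sequence_from_array(rng.uniform(0, 100, size=(n_frames, 106, 2)),
                                f"s{i}", f"r{i}", "PD" if i % 2 else "control")
            for i in range(2)
        ]
        return save_cohort(seqs, tmp_path / "cohort"), seqs

    def test_load_two_records(self, tmp_path, rng):
        manifest, seqs = self._write_cohort(tmp_path, rng)
        loaded = load_dataset(manifest)
        assert len(loaded) == 2
        assert all(s.n_frames == 50 for s in loaded)
        np.testing.assert_array_equal(loaded[0].as_array(), seqs[0].as_array())

    def test_label_trimming(self):
        assert normalize_label("PD ") == "PD"
        assert normalize_label(" control") == "control"
        with pytest.raises(ManifestError, match="unknown label"):
            normalize_label("unsure")

    def test_glob_matching_nothing_names_record(self, tmp_path):
        write_manifest(
            [{"subject_id": "s", "record_id": "ghost", "label": "PD",
              "frame_interval": 0.1, "path": "missing_*.json"}],
            tmp_path / "manifest.csv",
        )
        with pytest.raises(ManifestError, match="ghost"):
            load_dataset(tmp_path / "manifest.csv")

    def test_json_frame_glob(self, tmp_path, rng):
        frames_dir = tmp_path / "frames"
        frames_dir.mkdir()
        coords = rng.uniform(0, 500, size=(3, 106, 2))
        for i in range(3):
            _json_fixture(frames_dir / f"frame_{i:03d}.json", coords[i])
        write_manifest(
            [{"subject_id": "s", "record_id": "r", "label": "PD",
              "frame_interval": 0.1, "path": "frames/frame_*.json"}],
            tmp_path / "manifest.csv",
        )
        loaded = load_dataset(tmp_path / "manifest.csv")
        assert len(loaded) == 1
        np.testing.assert_array_equal(loaded[0].as_array(), coords)
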