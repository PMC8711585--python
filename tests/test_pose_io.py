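import json
import math

import numpy as np
import pytest

from pitchfatigue.errors import (
    DegenerateGeometryError,
    EmptyFrameError,
    MissingFrameError,
    PoseParseError,
    SchemaError,
)
from pitchfatigue.pose_io import (
    BODY_25_PARTS,
    COCO_18_PARTS,
    AngleConfig,
    GameSession,
    Keypoint,
    PitchEvent,
    PitchObservation,
    PoseFrame,
    build_session,
    elbow_valgus_angle,
    read_event_csv,
    read_feature_csv,
    read_openpose_frame,
    trunk_flexion_angle,
    write_event_csv,
    write_feature_csv,
    write_openpose_frame,
)
from pitchfatigue.simulate import simulate_games, SimConfig

from conftest import make_session


def frame_from(points, frame_id=0, timestamp=0.0):
    """PoseFrame from a name -> (x, y) mapping, all confidences 1."""
    return PoseFrame(
        frame_id=frame_id,
        timestamp=timestamp,
        keypoints={name: Keypoint(x, y, 1.0) for name, (x, y) in points.items()},
    )


def write_openpose_json(path, people_triplets, n_parts=25):
    people = [{"pose_keypoints_2d": list(flat)} for flat in people_triplets]
    path.write_text(json.dumps({"people": people}))


class TestReadOpenposeFrame:
    def test_body25_full_person(self, tmp_path):
        flat = []
        for i in range(25):
            flat.extend([float(i), float(2 * i), 0.9])
        path = tmp_path / "frame.json"
        write_openpose_json(path, [flat])
        frame = read_openpose_frame(path, "BODY_25")
        assert set(BODY_25_PARTS) <= set(frame.keypoints)
        assert len(frame.keypoints) == 25  # mid_hip is part of BODY_25
        assert frame.get("neck").x == 1.0 and frame.get("neck").y == 2.0

    def test_empty_people_error(self, tmp_path):
        path = tmp_path / "frame.json"
        path.write_text(json.dumps({"people": []}))
        with pytest.raises(EmptyFrameError):
            read_openpose_frame(path)

    def test_malformed_json_names_file(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(PoseParseError, match="bad.json"):
            read_openpose_frame(path)

    def test_wrong_triplet_count(self, tmp_path):
        path = tmp_path / "frame.json"
        write_openpose_json(path, [[1.0, 2.0, 0.5] * 10])
        with pytest.raises(PoseParseError):
            read_openpose_frame(path, "BODY_25")

    def test_two_people_highest_total_confidence_wins(self, tmp_path):
        # Oracle: manual sums of the confidence triplets.
        person_a = []
        person_b = []
        for i in range(25):
            person_a.extend([10.0 + i, 20.0, 0.4])
            person_b.extend([50.0 + i, 60.0, 0.7])
        assert sum(person_a[2::3]) < sum(person_b[2::3])
        path = tmp_path / "frame.json"
        write_openpose_json(path, [person_a, person_b])
        frame = read_openpose_frame(path)
        assert frame.get("nose").x == 50.0
        assert frame.get("nose").confidence == 0.7

    def test_coco18_synthesizes_mid_hip(self, tmp_path):
        flat = []
        for i, name in enumerate(COCO_18_PARTS):
            flat.extend([float(i), float(i), 1.0])
        path = tmp_path / "frame.json"
        write_openpose_json(path, [flat])
        frame = read_openpose_frame(path, "COCO-18")
        left = COCO_18_PARTS.index("left_hip")
        right = COCO_18_PARTS.index("right_hip")
        assert frame.get("mid_hip").x == pytest.approx((left + right) / 2)
        assert not frame.get("mid_hip").missing

    def test_absent_parts_become_confidence_zero(self, tmp_path):
        flat = []
        for i in range(25):
            conf = 0.0 if i == 4 else 0.8  # drop the right wrist
            flat.extend([float(i), float(i), conf])
        path = tmp_path / "frame.json"
        write_openpose_json(path, [flat])
        frame = read_openpose_frame(path)
        assert frame.get("right_wrist").missing

    def test_write_read_roundtrip(self, tmp_path):
        flat = []
        rng = np.random.default_rng(7)
        for _ in range(25):
            flat.extend([float(rng.uniform(0, 640)), float(rng.uniform(0, 480)), 1.0])
        path = tmp_path / "a.json"
        write_openpose_json(path, [flat])
        frame = read_openpose_frame(path)
        out = tmp_path / "b.json"
        write_openpose_frame(frame, out)
        again = read_openpose_frame(out)
        for name in BODY_25_PARTS:
            assert again.get(name).x == frame.get(name).x
            assert again.get(name).y == frame.get(name).y


class TestElbowAngle:
    def test_collinear_is_180(self):
        frame = frame_from({
            "right_shoulder": (0, 0), "right_elbow": (1, 0), "right_wrist": (2, 0),
        })
        assert elbow_valgus_angle(frame) == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        frame = frame_from({
            "right_shoulder": (0, 0), "right_elbow": (1, 0), "right_wrist": (1, 1),
        })
        assert elbow_valgus_angle(frame) == pytest.approx(90.0)

    def test_matches_law_of_cosines_oracle(self, rng):
        for _ in range(200):
            s, e, w = rng.uniform(-50, 50, size=(3, 2))
            if np.linalg.norm(s - e) < 1e-3 or np.linalg.norm(w - e) < 1e-3:
                continue
            frame = frame_from({
                "right_shoulder": tuple(s),
                "right_elbow": tuple(e),
                "right_wrist": tuple(w),
            })
            # Independent oracle: law of cosines on the triangle side lengths.
            a = np.linalg.norm(s - e)
            b = np.linalg.norm(w - e)
            c = np.linalg.norm(s - w)
            cos_angle = (a**2 + b**2 - c**2) / (2 * a * b)
            expected = math.degrees(math.acos(np.clip(cos_angle, -1, 1)))
            assert elbow_valgus_angle(frame) == pytest.approx(expected, abs=1e-9)

    def test_arm_elevation_horizontal_is_zero(self):
        frame = frame_from({"right_shoulder": (0, 0), "right_elbow": (5, 0)})
        assert elbow_valgus_angle(frame, definition="arm_elevation") == pytest.approx(0.0)

    def test_arm_elevation_raised_arm(self):
        # Elbow above the shoulder (smaller y) at 45 degrees.
        frame = frame_from({"right_shoulder": (0, 0), "right_elbow": (1, -1)})
        assert elbow_valgus_angle(frame, definition="arm_elevation") == pytest.approx(45.0)

    def test_low_confidence_returns_missing(self):
        frame = PoseFrame(0, 0.0, {
            "right_shoulder": Keypoint(0, 0, 1.0),
            "right_elbow": Keypoint(1, 0, 0.05),
            "right_wrist": Keypoint(2, 0, 1.0),
        })
        assert elbow_valgus_angle(frame) is None

    def test_coincident_points_degenerate(self):
        frame = frame_from({
            "right_shoulder": (1, 1), "right_elbow": (1, 1), "right_wrist": (2, 2),
        })
        with pytest.raises(DegenerateGeometryError):
            elbow_valgus_angle(frame)

    def test_left_handedness_uses_left_arm(self):
        frame = frame_from({
            "left_shoulder": (0, 0), "left_elbow": (1, 0), "left_wrist": (1, 1),
            "right_shoulder": (0, 0), "right_elbow": (1, 0), "right_wrist": (2, 0),
        })
        assert elbow_valgus_angle(frame, handedness="left") == pytest.approx(90.0)


class TestTrunkAngle:
    def test_collinear_is_180(self):
        frame = frame_from({
            "right_shoulder": (0, 0), "right_elbow": (0, -1), "right_hip": (0, 1),
        })
        assert trunk_flexion_angle(frame) == pytest.approx(180.0)

    def test_upright_trunk_vertical_is_zero(self):
        frame = frame_from({"mid_hip": (0, 1), "neck": (0, 0)})
        assert trunk_flexion_angle(frame, definition="trunk_vertical") == pytest.approx(0.0)

    def test_trunk_vertical_lean(self):
        frame = frame_from({"mid_hip": (0, 0), "neck": (1, -1)})
        assert trunk_flexion_angle(frame, definition="trunk_vertical") == pytest.approx(45.0)

    def test_missing_keypoint(self):
        frame = PoseFrame(0, 0.0, {
            "right_shoulder": Keypoint(0, 0, 1.0),
            "right_elbow": Keypoint(1, 0, 1.0),
            "right_hip": Keypoint(0, 1, 0.0),
        })
        assert trunk_flexion_angle(frame) is None


class TestRigidInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_angles_invariant_under_rigid_transforms(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.uniform(-30, 30, size=(5, 2))
        names = ("right_shoulder", "right_elbow", "right_wrist",
                 "right_hip", "mid_hip")
        base = frame_from(dict(zip(names, map(tuple, points))))
        c0 = elbow_valgus_angle(base)
        k0 = trunk_flexion_angle(base)

        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        scale = rng.uniform(0.2, 5.0)
        shift = rng.uniform(-100, 100, size=2)
        moved = scale * points @ rot.T + shift
        frame = frame_from(dict(zip(names, map(tuple, moved))))
        assert elbow_valgus_angle(frame) == pytest.approx(c0, abs=1e-9)
        assert trunk_flexion_angle(frame) == pytest.approx(k0, abs=1e-9)


class TestBuildSession:
    def _frames_at(self, times):
        return [
            frame_from(
                {
                    "right_shoulder": (0, 0), "right_elbow": (1, 0),
                    "right_wrist": (1, 1), "right_hip": (0, 1),
                },
                frame_id=i, timestamp=t,
            )
            for i, t in enumerate(times)
        ]

    def _events_at(self, times, game_id="g1"):
        return [
            PitchEvent(game_id=game_id, pitch_index=i + 1, release_timestamp=t)
            for i, t in enumerate(times)
        ]

    def test_interval_assignment(self):
        session = build_session(self._frames_at([0, 20, 50]),
                                self._events_at([0, 20, 50]))
        assert [o.t for o in session.observations] == [None, 20.0, 30.0]

    def test_single_pitch(self):
        session = build_session(self._frames_at([5.0]), self._events_at([5.0]))
        assert session.n_pitches == 1
        assert session.observations[0].t is None

    def test_interval_sum_telescopes(self, rng):
        times = np.cumsum(rng.uniform(5, 30, size=20))
        session = build_session(self._frames_at(times), self._events_at(times))
        total = sum(o.t for o in session.observations[1:])
        assert total == pytest.approx(times[-1] - times[0], abs=1e-12)

    def test_missing_frame_error_names_pitch(self):
        with pytest.raises(MissingFrameError, match="pitch 2"):
            build_session(self._frames_at([0.0]), self._events_at([0.0, 20.0]))

    def test_angles_computed_at_release(self):
        session = build_session(self._frames_at([0, 10]), self._events_at([0, 10]))
        assert session.observations[0].c == pytest.approx(90.0)
        assert session.observations[0].k == pytest.approx(90.0)


class TestFeatureCsv:
    def test_two_games(self, tmp_path):
        a = make_session([90.0, 91.0], [85.0, 84.0], [None, 20.0], game_id="a")
        b = make_session([92.0] * 3, [83.0] * 3, [None, 21.0, 22.0], game_id="b")
        path = tmp_path / "features.csv"
        write_feature_csv([a, b], path)
        sessions = read_feature_csv(path)
        assert [s.game_id for s in sessions] == ["a", "b"]
        assert [s.n_pitches for s in sessions] == [2, 3]

    def test_roundtrip_bit_identical(self, tmp_path):
        sessions, _ = simulate_games(SimConfig(n_pitches=100, n_games=1, seed=9))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_feature_csv(sessions, p1)
        write_feature_csv(read_feature_csv(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pitch_index_gap_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "game_id,pitch_index,elbow_angle_deg,trunk_angle_deg,interval_s\n"
            "g,1,90,85,\n"
            "g,2,90,85,20\n"
            "g,4,90,85,21\n"
        )
        with pytest.raises(SchemaError):
            read_feature_csv(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("game_id,pitch_index,elbow_angle_deg\ng,1,90\n")
        with pytest.raises(SchemaError):
            read_feature_csv(path)

    def test_event_csv_roundtrip(self, tmp_path):
        events = [
            PitchEvent("g", 1, 0.0),
            PitchEvent("g", 2, 17.5),
        ]
        path = tmp_path / "events.csv"
        write_event_csv(events, path)
        assert read_event_csv(path) == events


class TestDomainTypes:
    def test_angle_out_of_range_rejected(self):
        with pytest.raises(Exception):
            PitchObservation("g", 1, c=200.0, k=90.0, t=None)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(Exception):
            PitchObservation("g", 1, c=90.0, k=90.0, t=0.0)

    def test_missing_flags(self):
        obs = PitchObservation("g", 1, c=None, k=85.0, t=None)
        assert obs.missing_flags == {"c": True, "k": False, "t": True}

    def test_session_requires_contiguous_indices(self):
        obs = [
            PitchObservation("g", 1, 90.0, 85.0, None),
            PitchObservation("g", 3, 90.0, 85.0, 20.0),
        ]
        with pytest.raises(SchemaError):
            GameSession(game_id="g", observations=tuple(obs))
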