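"""Pose-keypoint ingestion and per-pitch kinematic features.

Reads OpenPose-dialect JSON keypoint files and pitch-event tables, computes
the two joint angles (elbow and trunk) at each pitch's release frame plus the
inter-pitch interval, and assembles per-game feature tables.

Coordinates follow the OpenPose image convention: origin at the top-left,
x rightward, y *downward*, units of pixels.  All angles are planar
(image-plane) angles in degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    EmptyFrameError,
    MissingFrameError,
    ParameterError,
    PoseParseError,
    SchemaError,
)

__all__ = [
    "Keypoint",
    "PoseFrame",
    "PitchEvent",
    "PitchObservation",
    "GameSession",
    "AngleConfig",
    "read_openpose_frame",
    "write_openpose_frame",
    "elbow_valgus_angle",
    "trunk_flexion_angle",
    "build_session",
    "read_feature_csv",
    "write_feature_csv",
    "read_event_csv",
    "write_event_csv",
]

# Published part orderings for the two supported OpenPose output dialects.
BODY_25_PARTS = (
    "nose", "neck",
    "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist",
    "mid_hip", "right_hip", "right_knee", "right_ankle",
    "left_hip", "left_knee", "left_ankle",
    "right_eye", "left_eye", "right_ear", "left_ear",
    "left_big_toe", "left_small_toe", "left_heel",
    "right_big_toe", "right_small_toe", "right_heel",
)
COCO_18_PARTS = (
    "nose", "neck",
    "right_shoulder", "right_elbow", "right_wrist",
    "left_shoulder", "left_elbow", "left_wrist",
    "right_hip", "right_knee", "right_ankle",
    "left_hip", "left_knee", "left_ankle",
    "right_eye", "left_eye", "right_ear", "left_ear",
)
DIALECTS = {"BODY_25": BODY_25_PARTS, "COCO_18": COCO_18_PARTS}

FEATURE_COLUMNS = (
    "game_id", "pitch_index", "elbow_angle_deg", "trunk_angle_deg", "interval_s",
)
EVENT_COLUMNS = ("game_id", "pitch_index", "release_timestamp_s")

ELBOW_DEFINITIONS = ("joint_interior", "arm_elevation")
TRUNK_DEFINITIONS = ("shoulder_trunk", "trunk_vertical")


@dataclass(frozen=True)
class Keypoint:
    """A single named 2-D keypoint in image pixels.

    ``confidence`` is in [0, 1]; a confidence of 0 marks a missing part whose
    coordinates are not interpretable.
    """

    x: float
    y: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ParameterError(
                f"keypoint confidence {self.confidence} outside [0, 1]"
            )

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


MISSING_KEYPOINT = Keypoint(float("nan"), float("nan"), 0.0)


@dataclass(frozen=True)
class PoseFrame:
    """Named keypoints for one video frame."""

    frame_id: int
    timestamp: float
    keypoints: Mapping[str, Keypoint]

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ParameterError(f"negative timestamp {self.timestamp}")

    def get(self, part: str) -> Keypoint:
        return self.keypoints.get(part, MISSING_KEYPOINT)


@dataclass(frozen=True)
class PitchEvent:
    """One pitch release, identified by its ball-apex frame time."""

    game_id: str
    pitch_index: int
    release_timestamp: float


@dataclass(frozen=True)
class PitchObservation:
    """One pitch's feature triple (``None`` marks a missing feature).

    c : elbow valgus angle, degrees
    k : trunk flexion angle, degrees
    t : time since the previous pitch, seconds (missing for pitch 1)
    """

    game_id: str
    pitch_index: int
    c: float | None
    k: float | None
    t: float | None

    def __post_init__(self) -> None:
        for name, value in (("c", self.c), ("k", self.k)):
            if value is not None and not 0.0 <= value <= 180.0:
                raise ParameterError(f"angle {name}={value} outside [0, 180]")
        if self.t is not None and self.t <= 0:
            raise ParameterError(f"non-positive interval t={self.t}")

    @property
    def missing_flags(self) -> dict[str, bool]:
        return {"c": self.c is None, "k": self.k is None, "t": self.t is None}


@dataclass(frozen=True)
class GameSession:
    """Ordered per-pitch observations for one game."""

    game_id: str
    observations: tuple[PitchObservation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        indices = [obs.pitch_index for obs in self.observations]
        if indices != list(range(1, len(indices) + 1)):
            raise SchemaError(
                f"game {self.game_id!r}: pitch indices must be 1..N without "
                f"gaps, got {indices}"
            )

    @property
    def n_pitches(self) -> int:
        return len(self.observations)

    def feature_arrays(self) -> dict[str, np.ndarray]:
        """Features as float arrays with NaN for missing values."""
        to_nan = lambda v: float("nan") if v is None else float(v)
        return {
            "elbow": np.array([to_nan(o.c) for o in self.observations]),
            "trunk": np.array([to_nan(o.k) for o in self.observations]),
            "interval": np.array([to_nan(o.t) for o in self.observations]),
        }


@dataclass(frozen=True)
class AngleConfig:
    """Angle definitions and thresholds used during feature extraction."""

    handedness: str = "right"
    elbow_definition: str = "joint_interior"
    trunk_definition: str = "shoulder_trunk"
    confidence_threshold: float = 0.1
    timestamp_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.handedness not in ("left", "right"):
            raise ParameterError(f"handedness {self.handedness!r}")
        if self.elbow_definition not in ELBOW_DEFINITIONS:
            raise ParameterError(f"elbow definition {self.elbow_definition!r}")
        if self.trunk_definition not in TRUNK_DEFINITIONS:
            raise ParameterError(f"trunk definition {self.trunk_definition!r}")


def _normalize_dialect(dialect: str) -> str:
    key = dialect.upper().replace("-", "_")
    if key not in DIALECTS:
        raise ParameterError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}"
        )
    return key


def read_openpose_frame(
    path: str | Path,
    dialect: str = "BODY_25",
    frame_id: int = 0,
    timestamp: float = 0.0,
) -> PoseFrame:
    """Read one OpenPose-dialect JSON keypoint file into a :class:`PoseFrame`.

    The file holds a top-level ``"people"`` array; each person carries
    ``"pose_keypoints_2d"`` as a flat ``[x, y, confidence, ...]`` list.  When
    several people are present the one with the highest summed keypoint
    confidence is selected (the pitcher is the dominant subject).  For the
    COCO_18 dialect a ``mid_hip`` point is synthesized as the midpoint of the
    two hips when both are present.
    """
    parts = DIALECTS[_normalize_dialect(dialect)]
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PoseParseError(f"malformed keypoint JSON in {path}: {exc}") from exc
    people = payload.get("people")
    if people is None:
        raise PoseParseError(f"{path}: missing 'people' array")
    if not people:
        raise EmptyFrameError(f"{path}: no people detected")

    def triplets(person: Mapping) -> np.ndarray:
        flat = person.get("pose_keypoints_2d")
        if flat is None or len(flat) != 3 * len(parts):
            raise PoseParseError(
                f"{path}: expected {3 * len(parts)} pose_keypoints_2d values"
            )
        return np.asarray(flat, dtype=float).reshape(-1, 3)

    arrays = [triplets(p) for p in people]
    chosen = arrays[int(np.argmax([a[:, 2].sum() for a in arrays]))]

    keypoints = {
        name: Keypoint(float(x), float(y), float(conf))
        for name, (x, y, conf) in zip(parts, chosen)
    }
    if "mid_hip" not in keypoints:
        left, right = keypoints["left_hip"], keypoints["right_hip"]
        if left.missing or right.missing:
            keypoints["mid_hip"] = MISSING_KEYPOINT
        else:
            keypoints["mid_hip"] = Keypoint(
                (left.x + right.x) / 2.0,
                (left.y + right.y) / 2.0,
                min(left.confidence, right.confidence),
            )
    return PoseFrame(frame_id=frame_id, timestamp=timestamp, keypoints=keypoints)


def write_openpose_frame(
    frame: PoseFrame, path: str | Path, dialect: str = "BODY_25"
) -> None:
    """Write a frame back out in the OpenPose JSON dialect."""
    parts = DIALECTS[_normalize_dialect(dialect)]
    flat: list[float] = []
    for name in parts:
        kp = frame.get(name)
        if kp.missing:
            flat.extend([0.0, 0.0, 0.0])
        else:
            flat.extend([kp.x, kp.y, kp.confidence])
    Path(path).write_text(
        json.dumps({"version": 1.3, "people": [{"pose_keypoints_2d": flat}]})
    )


def _vector(a: Keypoint, b: Keypoint) -> np.ndarray:
    """Vector from keypoint ``a`` to keypoint ``b``."""
    return b.as_array() - a.as_array()


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length vector between keypoints")
    cosine = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosine))))


def _resolve(
    frame: PoseFrame, names: Sequence[str], threshold: float
) -> list[Keypoint] | None:
    """Fetch keypoints, or ``None`` if any falls below the confidence bar."""
    points = [frame.get(name) for name in names]
    if any(kp.confidence < threshold for kp in points):
        return None
    return points


def elbow_valgus_angle(
    frame: PoseFrame,
    handedness: str = "right",
    definition: str = "joint_interior",
    confidence_threshold: float = 0.1,
) -> float | None:
    """Elbow angle of the throwing arm, in degrees, or ``None`` if missing.

    ``joint_interior`` is the interior angle at the elbow between the
    elbow->shoulder and elbow->wrist vectors.  ``arm_elevation`` is the angle
    of the shoulder->elbow segment relative to the image horizontal (both in
    [0, 180]).
    """
    side = handedness
    if definition == "joint_interior":
        points = _resolve(
            frame,
            (f"{side}_shoulder", f"{side}_elbow", f"{side}_wrist"),
            confidence_threshold,
        )
        if points is None:
            return None
        shoulder, elbow, wrist = points
        return _angle_between(_vector(elbow, shoulder), _vector(elbow, wrist))
    if definition == "arm_elevation":
        points = _resolve(
            frame, (f"{side}_shoulder", f"{side}_elbow"), confidence_threshold
        )
        if points is None:
            return None
        shoulder, elbow = points
        return _angle_between(_vector(shoulder, elbow), np.array([1.0, 0.0]))
    raise ParameterError(f"elbow definition {definition!r}")


def trunk_flexion_angle(
    frame: PoseFrame,
    handedness: str = "right",
    definition: str = "shoulder_trunk",
    confidence_threshold: float = 0.1,
) -> float | None:
    """Trunk angle in degrees, or ``None`` if required keypoints are missing.

    ``shoulder_trunk`` is the angle at the throwing shoulder between the
    shoulder->elbow and shoulder->hip (same side) vectors.  ``trunk_vertical``
    is the angle between the mid-hip->neck axis and the image vertical (0 for
    an upright trunk; remember y grows downward).
    """
    side = handedness
    if definition == "shoulder_trunk":
        points = _resolve(
            frame,
            (f"{side}_shoulder", f"{side}_elbow", f"{side}_hip"),
            confidence_threshold,
        )
        if points is None:
            return None
        shoulder, elbow, hip = points
        return _angle_between(_vector(shoulder, elbow), _vector(shoulder, hip))
    if definition == "trunk_vertical":
        points = _resolve(frame, ("mid_hip", "neck"), confidence_threshold)
        if points is None:
            return None
        mid_hip, neck = points
        # Image vertical "up" is -y.
        return _angle_between(_vector(mid_hip, neck), np.array([0.0, -1.0]))
    raise ParameterError(f"trunk definition {definition!r}")


def build_session(
    frames: Iterable[PoseFrame],
    events: Sequence[PitchEvent],
    config: AngleConfig | None = None,
) -> GameSession:
    """Assemble a per-pitch feature table from frames and pitch events.

    The two angles are computed at each event's release frame.  The interval
    ``t`` of pitch i is ``release(i) - release(i-1)`` — attached to the later
    pitch so that detection uses only past information; pitch 1's ``t`` is
    missing.
    """
    config = config or AngleConfig()
    events = sorted(events, key=lambda e: e.pitch_index)
    if not events:
        raise ParameterError("no pitch events supplied")
    game_ids = {e.game_id for e in events}
    if len(game_ids) != 1:
        raise SchemaError(f"events span multiple games: {sorted(game_ids)}")
    timestamps = [e.release_timestamp for e in events]
    if any(b <= a for a, b in zip(timestamps, timestamps[1:])):
        raise SchemaError("release timestamps must be strictly increasing")

    frame_list = sorted(frames, key=lambda f: f.timestamp)
    frame_times = np.array([f.timestamp for f in frame_list])

    observations = []
    previous_time: float | None = None
    for event in events:
        if frame_times.size:
            idx = int(np.argmin(np.abs(frame_times - event.release_timestamp)))
            gap = abs(frame_times[idx] - event.release_timestamp)
        else:
            gap = float("inf")
        if gap > config.timestamp_tolerance:
            raise MissingFrameError(
                f"pitch {event.pitch_index}: no frame at "
                f"t={event.release_timestamp}"
            )
        frame = frame_list[idx]
        c = elbow_valgus_angle(
            frame, config.handedness, config.elbow_definition,
            config.confidence_threshold,
        )
        k = trunk_flexion_angle(
            frame, config.handedness, config.trunk_definition,
            config.confidence_threshold,
        )
        t = None if previous_time is None else event.release_timestamp - previous_time
        observations.append(
            PitchObservation(
                game_id=event.game_id, pitch_index=event.pitch_index,
                c=c, k=k, t=t,
            )
        )
        previous_time = event.release_timestamp
    return GameSession(game_id=events[0].game_id, observations=tuple(observations))


def write_feature_csv(sessions: Sequence[GameSession], path: str | Path) -> None:
    """Write sessions to the feature CSV schema (empty cells mean missing)."""
    rows = [
        {
            "game_id": obs.game_id,
            "pitch_index": obs.pitch_index,
            "elbow_angle_deg": obs.c,
            "trunk_angle_deg": obs.k,
            "interval_s": obs.t,
        }
        for session in sessions
        for obs in session.observations
    ]
    pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)).to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> list[GameSession]:
    """Read a feature CSV into per-game sessions, validating the schema."""
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"unreadable feature CSV {path}: {exc}") from exc
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")

    def cell(value: object) -> float | None:
        return None if pd.isna(value) else float(value)

    sessions = []
    for game_id in table["game_id"].drop_duplicates():
        block = table[table["game_id"] == game_id]
        observations = tuple(
            PitchObservation(
                game_id=str(game_id),
                pitch_index=int(row.pitch_index),
                c=cell(row.elbow_angle_deg),
                k=cell(row.trunk_angle_deg),
                t=cell(row.interval_s),
            )
            for row in block.itertuples()
        )
        sessions.append(GameSession(game_id=str(game_id), observations=observations))
    return sessions


def write_event_csv(events: Sequence[PitchEvent], path: str | Path) -> None:
    rows = [
        {
            "game_id": e.game_id,
            "pitch_index": e.pitch_index,
            "release_timestamp_s": e.release_timestamp,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def read_event_csv(path: str | Path) -> list[PitchEvent]:
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"unreadable event CSV {path}: {exc}") from exc
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return [
        PitchEvent(
            game_id=str(row.game_id),
            pitch_index=int(row.pitch_index),
            release_timestamp=float(row.release_timestamp_s),
        )
        for row in table.itertuples()
    ]
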