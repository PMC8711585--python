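"""Seeded synthetic pitching sessions and pose frames.

Two generators make the whole pipeline testable without external data:

* :func:`simulate_session` draws per-pitch feature streams from two normal
  regimes (non-fatigue before a known onset pitch, fatigue after), with the
  directional shifts expected under fatigue — elbow angle up, trunk angle
  down, inter-pitch interval up — and emits the ground truth alongside.
* :func:`synthesize_frame` places 2-D keypoints realizing prescribed elbow
  and trunk angles exactly, so the angle operations can be round-tripped.

Default regime magnitudes are plausible fixtures, not biology: elbow
95->110 deg, trunk 100->85 deg, interval 18->25 s.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConstructionError, ParameterError
from .pose_io import (
    GameSession,
    Keypoint,
    PitchEvent,
    PitchObservation,
    PoseFrame,
)

__all__ = [
    "SimConfig",
    "simulate_session",
    "simulate_games",
    "synthesize_frame",
    "session_frames",
    "write_ground_truth_json",
]

# Guard against binary-float noise in onset_fraction * N before ceiling.
_CEIL_EPS = 1e-9


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic session generator.

    Means/SDs are (non-fatigue, fatigue) pairs per feature; angles in
    degrees, intervals in seconds.  ``transition`` is "abrupt" (regime
    switch at the onset pitch) or "logistic" (means and SDs blend over
    ``ramp_width`` pitches).
    """

    n_pitches: int = 100
    n_games: int = 7
    onset_fraction: float = 0.7
    elbow_nf: tuple[float, float] = (95.0, 4.0)
    elbow_f: tuple[float, float] = (110.0, 4.0)
    trunk_nf: tuple[float, float] = (100.0, 4.0)
    trunk_f: tuple[float, float] = (85.0, 4.0)
    interval_nf: tuple[float, float] = (18.0, 3.0)
    interval_f: tuple[float, float] = (25.0, 3.0)
    transition: str = "abrupt"
    ramp_width: float = 5.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pitches < 2:
            raise ParameterError(f"n_pitches {self.n_pitches} must be >= 2")
        if self.n_games < 1:
            raise ParameterError(f"n_games {self.n_games} must be >= 1")
        if not 0.0 < self.onset_fraction <= 1.0:
            raise ParameterError(
                f"onset_fraction {self.onset_fraction} outside (0, 1]"
            )
        for name in ("elbow_nf", "elbow_f", "trunk_nf", "trunk_f",
                     "interval_nf", "interval_f"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} SD {sd} must be >= 0")
        if self.transition not in ("abrupt", "logistic"):
            raise ParameterError(f"transition {self.transition!r}")
        if self.ramp_width <= 0:
            raise ParameterError(f"ramp_width {self.ramp_width} must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError(
                f"missing_rate {self.missing_rate} outside [0, 1)"
            )

    @property
    def onset_pitch(self) -> int:
        """Last pitch drawn from the non-fatigue regime."""
        return int(math.ceil(self.onset_fraction * self.n_pitches - _CEIL_EPS))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        kwargs = {k: v for k, v in payload.items() if k in known}
        for name in ("elbow_nf", "elbow_f", "trunk_nf", "trunk_f",
                     "interval_nf", "interval_f"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


def _regime_weights(config: SimConfig) -> np.ndarray:
    """Fatigue-regime mixing weight per pitch (0 = non-fatigue, 1 = fatigue)."""
    indices = np.arange(1, config.n_pitches + 1, dtype=float)
    onset = config.onset_pitch
    if config.transition == "abrupt":
        return (indices > onset).astype(float)
    if config.onset_fraction >= 1.0:
        return np.zeros_like(indices)
    z = np.clip((indices - onset - 0.5) / config.ramp_width, -60.0, 60.0)
    return 1.0 / (1.0 + np.exp(-z))


def _draw(
    rng: np.random.Generator,
    weights: np.ndarray,
    nf: tuple[float, float],
    f: tuple[float, float],
    positive: bool = False,
) -> np.ndarray:
    means = nf[0] + weights * (f[0] - nf[0])
    sds = nf[1] + weights * (f[1] - nf[1])
    values = rng.normal(means, sds)
    if positive:
        for _ in range(1000):
            bad = values <= 0
            if not bad.any():
                break
            values[bad] = rng.normal(means[bad], sds[bad])
        else:
            raise ParameterError("could not draw positive intervals")
    return values


def simulate_session(
    config: SimConfig,
    game_id: str = "sim-1",
    rng: np.random.Generator | None = None,
) -> tuple[GameSession, dict]:
    """Generate one session plus its ground-truth record.

    Pitch i draws each feature from the non-fatigue normal while
    ``i <= ceil(onset_fraction * N)`` and from the fatigue normal after
    (blended means for the logistic transition).  Intervals are resampled
    until positive; each feature is dropped independently at
    ``missing_rate``; pitch 1's interval is always missing.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    weights = _regime_weights(config)
    elbow = _draw(rng, weights, config.elbow_nf, config.elbow_f)
    trunk = _draw(rng, weights, config.trunk_nf, config.trunk_f)
    interval = _draw(rng, weights, config.interval_nf, config.interval_f,
                     positive=True)
    elbow = np.clip(elbow, 0.0, 180.0)
    trunk = np.clip(trunk, 0.0, 180.0)

    drop = rng.random((config.n_pitches, 3)) < config.missing_rate

    timestamps = np.concatenate([[0.0], np.cumsum(interval[1:])])
    onset = config.onset_pitch
    observations = []
    for i in range(config.n_pitches):
        observations.append(
            PitchObservation(
                game_id=game_id,
                pitch_index=i + 1,
                c=None if drop[i, 0] else float(elbow[i]),
                k=None if drop[i, 1] else float(trunk[i]),
                t=None if (i == 0 or drop[i, 2]) else float(interval[i]),
            )
        )
    session = GameSession(game_id=game_id, observations=tuple(observations))
    ground_truth = {
        "game_id": game_id,
        "onset_pitch": onset,
        "first_fatigue_pitch": onset + 1 if onset < config.n_pitches else None,
        "regime_labels": [int(w > 0.5) for w in weights],
        "true_elbow": [float(v) for v in elbow],
        "true_trunk": [float(v) for v in trunk],
        "true_interval": [None] + [float(v) for v in interval[1:]],
        "release_timestamps": [float(v) for v in timestamps],
        "config": config.to_dict(),
    }
    return session, ground_truth


def simulate_games(
    config: SimConfig, game_prefix: str = "sim"
) -> tuple[list[GameSession], list[dict]]:
    """Generate ``config.n_games`` sessions from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    sessions, truths = [], []
    for g in range(config.n_games):
        session, truth = simulate_session(
            config, game_id=f"{game_prefix}-{g + 1}", rng=rng
        )
        sessions.append(session)
        truths.append(truth)
    return sessions, truths


def _rotate(vector: np.ndarray, degrees_ccw: float) -> np.ndarray:
    rad = math.radians(degrees_ccw)
    c, s = math.cos(rad), math.sin(rad)
    return np.array([c * vector[0] - s * vector[1],
                     s * vector[0] + c * vector[1]])


def synthesize_frame(
    target_elbow_angle: float,
    target_trunk_angle: float,
    handedness: str = "right",
    elbow_definition: str = "joint_interior",
    trunk_definition: str = "shoulder_trunk",
    frame_id: int = 0,
    timestamp: float = 0.0,
    origin: tuple[float, float] = (320.0, 240.0),
    scale: float = 80.0,
) -> PoseFrame:
    """Place keypoints so the angle operations return the targets exactly.

    Works for any combination of the elbow definitions (joint_interior /
    arm_elevation) and trunk definitions (shoulder_trunk / trunk_vertical);
    every emitted keypoint has confidence 1.
    """
    for name, target in (
        ("elbow", target_elbow_angle), ("trunk", target_trunk_angle)
    ):
        if not 0.0 < target <= 180.0:
            raise ConstructionError(
                f"target {name} angle {target} outside (0, 180]"
            )
    if handedness not in ("left", "right"):
        raise ParameterError(f"handedness {handedness!r}")
    if scale <= 0:
        raise ParameterError(f"scale {scale} must be > 0")

    ox, oy = origin
    L = scale
    neck = np.array([ox, oy])
    side = 1.0 if handedness == "right" else -1.0
    shoulder = neck + np.array([side * L / 2.0, 0.0])

    # Upper-arm direction (shoulder -> elbow), in image coords (y down).
    if elbow_definition == "arm_elevation":
        rad = math.radians(target_elbow_angle)
        dir_se = np.array([math.cos(rad), -math.sin(rad)])
    elif elbow_definition == "joint_interior":
        dir_se = np.array([0.0, 1.0])
    else:
        raise ParameterError(f"elbow definition {elbow_definition!r}")
    elbow = shoulder + L * dir_se

    if elbow_definition == "joint_interior":
        wrist = elbow + L * _rotate(-dir_se, target_elbow_angle)
    else:
        wrist = elbow + np.array([0.6 * L, 0.0])

    if trunk_definition == "shoulder_trunk":
        throw_hip = shoulder + 1.2 * L * _rotate(dir_se, target_trunk_angle)
        mid_hip = neck + np.array([0.0, 1.5 * L])
    elif trunk_definition == "trunk_vertical":
        rad = math.radians(target_trunk_angle)
        # mid_hip -> neck direction at the target angle from image "up".
        axis = np.array([math.sin(rad), -math.cos(rad)])
        mid_hip = neck - 1.5 * L * axis
        throw_hip = mid_hip + np.array([side * L / 4.0, 0.0])
    else:
        raise ParameterError(f"trunk definition {trunk_definition!r}")
    other_hip = 2.0 * mid_hip - throw_hip

    other_shoulder = neck - (shoulder - neck)
    other_elbow = other_shoulder + np.array([0.0, L])
    other_wrist = other_elbow + np.array([-side * 0.6 * L, 0.0])
    nose = neck + np.array([0.0, -L / 2.0])

    def kp(point: np.ndarray) -> Keypoint:
        return Keypoint(float(point[0]), float(point[1]), 1.0)

    this, other = handedness, "left" if handedness == "right" else "right"
    keypoints = {
        "nose": kp(nose),
        "neck": kp(neck),
        f"{this}_shoulder": kp(shoulder),
        f"{this}_elbow": kp(elbow),
        f"{this}_wrist": kp(wrist),
        f"{other}_shoulder": kp(other_shoulder),
        f"{other}_elbow": kp(other_elbow),
        f"{other}_wrist": kp(other_wrist),
        f"{this}_hip": kp(throw_hip),
        f"{other}_hip": kp(other_hip),
        "mid_hip": kp(mid_hip),
    }
    return PoseFrame(frame_id=frame_id, timestamp=timestamp, keypoints=keypoints)


def session_frames(
    session: GameSession,
    handedness: str = "right",
    elbow_definition: str = "joint_interior",
    trunk_definition: str = "shoulder_trunk",
) -> tuple[list[PoseFrame], list[PitchEvent]]:
    """Realize a feature session as pose frames plus a pitch-event table.

    Release timestamps are reconstructed from the intervals (pitch 1 at
    t = 0).  Requires a session with no missing features beyond pitch 1's
    interval.
    """
    frames, events = [], []
    timestamp = 0.0
    for obs in session.observations:
        if obs.c is None or obs.k is None:
            raise ConstructionError(
                f"pitch {obs.pitch_index}: cannot synthesize a frame for "
                "missing angles"
            )
        if obs.pitch_index > 1:
            if obs.t is None:
                raise ConstructionError(
                    f"pitch {obs.pitch_index}: missing interval"
                )
            timestamp += obs.t
        frames.append(
            synthesize_frame(
                obs.c, obs.k,
                handedness=handedness,
                elbow_definition=elbow_definition,
                trunk_definition=trunk_definition,
                frame_id=obs.pitch_index - 1,
                timestamp=timestamp,
            )
        )
        events.append(
            PitchEvent(
                game_id=session.game_id,
                pitch_index=obs.pitch_index,
                release_timestamp=timestamp,
            )
        )
    return frames, events


def write_ground_truth_json(truths: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(truths), indent=2, sort_keys=True))
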