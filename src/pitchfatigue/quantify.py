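"""Fatigue quantification: interval split, feature bounds, piecewise scores.

A session of N pitches is split by the fatigue interval index ``alpha`` into a
non-fatigue prefix of ``floor(alpha * N)`` pitches and a fatigue suffix.  For
each feature the mean-plus-SD of the two regimes defines the knots ``x``
(non-fatigue side) and ``y`` (fatigue side) of a piecewise-linear map taking a
raw feature value to a unitless fatigue value in [0, 1]:

* elbow angle rises with fatigue  -> ramp up from x1 to y1 (y1 > x1 required);
* trunk angle falls with fatigue  -> ramp up from x2 down to y2 (x2 > y2);
* pitch interval lengthens        -> ramp up from x3 to y3 (y3 > x3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateBoundsError, InsufficientDataError, ParameterError
from .pose_io import GameSession

__all__ = [
    "FEATURES",
    "FeatureStats",
    "FeatureBounds",
    "PitchScore",
    "split_intervals",
    "interval_bounds",
    "fatigue_value_elbow",
    "fatigue_value_trunk",
    "fatigue_value_interval",
    "score_session",
    "write_bounds_json",
    "read_bounds_json",
]

FEATURES = ("elbow", "trunk", "interval")

# Direction each feature shifts under fatigue: +1 up-shifting, -1 down-shifting.
_DIRECTIONS = {"elbow": +1, "trunk": -1, "interval": +1}

# Tolerance absorbing binary-float representation noise in alpha * N
# (e.g. 0.7 * 7 == 4.8999999999999995) before flooring.
_FLOOR_EPS = 1e-9


@dataclass(frozen=True)
class FeatureStats:
    """Interval statistics and derived knots for one feature.

    ``x = nf_mean + nf_sd`` (non-fatigue knot), ``y = f_mean + f_sd``
    (fatigue knot); units are degrees for the angles, seconds for the
    interval.
    """

    nf_mean: float
    nf_sd: float
    f_mean: float
    f_sd: float
    x: float
    y: float


@dataclass(frozen=True)
class FeatureBounds:
    """Per-feature knots estimated from one training session."""

    elbow: FeatureStats
    trunk: FeatureStats
    interval: FeatureStats

    def stats(self, feature: str) -> FeatureStats:
        if feature not in FEATURES:
            raise ParameterError(f"unknown feature {feature!r}")
        return getattr(self, feature)

    def orientation_valid(self, feature: str) -> bool:
        """True when the fatigue knot lies on the expected side of x."""
        s = self.stats(feature)
        return s.y > s.x if _DIRECTIONS[feature] > 0 else s.x > s.y

    def to_dict(self) -> dict:
        return {
            feature: {
                "nf_mean": s.nf_mean, "nf_sd": s.nf_sd,
                "f_mean": s.f_mean, "f_sd": s.f_sd,
                "x": s.x, "y": s.y,
            }
            for feature in FEATURES
            for s in (self.stats(feature),)
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FeatureBounds":
        return cls(**{
            feature: FeatureStats(**payload[feature]) for feature in FEATURES
        })


@dataclass(frozen=True)
class PitchScore:
    """Per-pitch fatigue values (``None`` marks a missing feature)."""

    pitch_index: int
    a_elbow: float | None
    a_trunk: float | None
    a_interval: float | None
    m_total: float | None = None  # filled by the detect stage

    def values(self) -> tuple[float | None, float | None, float | None]:
        return (self.a_elbow, self.a_trunk, self.a_interval)


def split_intervals(n_pitches: int, alpha: float) -> tuple[int, int]:
    """Split N pitches into (non-fatigue, fatigue) counts at index ``alpha``.

    The non-fatigue prefix holds ``floor(alpha * N)`` pitches; e.g. 100
    pitches at alpha 0.6 give (60, 40).
    """
    if n_pitches < 2:
        raise ParameterError(f"need at least 2 pitches, got {n_pitches}")
    if not 0.0 < alpha <= 1.0:
        raise ParameterError(f"alpha {alpha} outside (0, 1]")
    n_nonfatigue = int(math.floor(alpha * n_pitches + _FLOOR_EPS))
    return n_nonfatigue, n_pitches - n_nonfatigue


def _regime_stats(values: np.ndarray, feature: str, regime: str, ddof: int) -> tuple[float, float]:
    present = values[~np.isnan(values)]
    if present.size < 2:
        raise InsufficientDataError(
            f"{regime} interval has {present.size} present value(s) for "
            f"feature {feature!r}; need at least 2"
        )
    return float(np.mean(present)), float(np.std(present, ddof=ddof))


def interval_bounds(
    session: GameSession,
    alpha: float,
    ddof: int = 1,
    symmetric_bounds: bool = False,
) -> FeatureBounds:
    """Estimate per-feature knots from one session's alpha-split.

    Uses the sample SD (``ddof=1``) by default.  With ``symmetric_bounds``
    the fatigue-side knot of down-shifting features (trunk) uses mean - SD
    instead of mean + SD.
    """
    n_nf, _ = split_intervals(session.n_pitches, alpha)
    arrays = session.feature_arrays()
    stats = {}
    for feature in FEATURES:
        values = arrays[feature]
        nf_mean, nf_sd = _regime_stats(values[:n_nf], feature, "non-fatigue", ddof)
        f_mean, f_sd = _regime_stats(values[n_nf:], feature, "fatigue", ddof)
        f_sign = -1.0 if (symmetric_bounds and _DIRECTIONS[feature] < 0) else 1.0
        stats[feature] = FeatureStats(
            nf_mean=nf_mean, nf_sd=nf_sd, f_mean=f_mean, f_sd=f_sd,
            x=nf_mean + nf_sd, y=f_mean + f_sign * f_sd,
        )
    return FeatureBounds(**stats)


def _ramp(value: float, low: float, high: float) -> float:
    """Linear ramp from 0 at ``low`` to 1 at ``high`` (low < high)."""
    if value < low:
        return 0.0
    if value > high:
        return 1.0
    return (value - low) / (high - low)


def _check_orientation(bounds: FeatureBounds, feature: str, degenerate: str) -> bool:
    """Returns True when scoring can proceed, False for step-mode fallback."""
    if bounds.orientation_valid(feature):
        return True
    if degenerate == "step":
        return False
    s = bounds.stats(feature)
    raise DegenerateBoundsError(
        f"feature {feature!r}: knots x={s.x:.6g}, y={s.y:.6g} have zero or "
        "wrong-signed ramp width"
    )


def fatigue_value_elbow(
    c: float, bounds: FeatureBounds, degenerate: str = "error"
) -> float:
    """Fatigue value A1 for elbow angle ``c``: 0 below x1, 1 above y1."""
    s = bounds.elbow
    if not _check_orientation(bounds, "elbow", degenerate):
        return 1.0 if c > s.x else 0.0
    return _ramp(c, s.x, s.y)


def fatigue_value_trunk(
    k: float, bounds: FeatureBounds, degenerate: str = "error"
) -> float:
    """Fatigue value A2 for trunk angle ``k``: 0 above x2, 1 below y2."""
    s = bounds.trunk
    if not _check_orientation(bounds, "trunk", degenerate):
        return 1.0 if k < s.x else 0.0
    if k > s.x:
        return 0.0
    if k < s.y:
        return 1.0
    return (s.x - k) / (s.x - s.y)


def fatigue_value_interval(
    t: float, bounds: FeatureBounds, degenerate: str = "error"
) -> float:
    """Fatigue value A3 for pitch interval ``t``: 0 below x3, 1 above y3."""
    s = bounds.interval
    if not _check_orientation(bounds, "interval", degenerate):
        return 1.0 if t > s.x else 0.0
    return _ramp(t, s.x, s.y)


def score_session(
    session: GameSession,
    bounds: FeatureBounds,
    degenerate: str = "error",
) -> list[PitchScore]:
    """Map every pitch's features to fatigue values A1..A3.

    Missing features yield missing fatigue values; the other features of the
    pitch are still scored.
    """
    if degenerate not in ("error", "step"):
        raise ParameterError(f"degenerate mode {degenerate!r}")
    scores = []
    for obs in session.observations:
        scores.append(
            PitchScore(
                pitch_index=obs.pitch_index,
                a_elbow=None if obs.c is None
                else fatigue_value_elbow(obs.c, bounds, degenerate),
                a_trunk=None if obs.k is None
                else fatigue_value_trunk(obs.k, bounds, degenerate),
                a_interval=None if obs.t is None
                else fatigue_value_interval(obs.t, bounds, degenerate),
            )
        )
    return scores


def write_bounds_json(
    bounds_by_game: Mapping[str, FeatureBounds], path: str | Path
) -> None:
    """Persist per-game bounds (the flat-file player-information store)."""
    payload = {game: b.to_dict() for game, b in bounds_by_game.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_bounds_json(path: str | Path) -> dict[str, FeatureBounds]:
    payload = json.loads(Path(path).read_text())
    return {game: FeatureBounds.from_dict(d) for game, d in payload.items()}
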