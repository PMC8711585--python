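"""Total fatigue index and fatigue-point detection.

Per-pitch fatigue values A1..A3 are combined into a weighted total index
``M_total`` expressed on a percent scale (so a threshold of 50 means
half-maximal fatigue), and the fatigue point R of a game is the first pitch
whose M_total reaches the threshold T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParameterError
from .pose_io import GameSession
from .quantify import FeatureBounds, PitchScore, score_session, split_intervals

__all__ = [
    "ScoreParams",
    "DetectionResult",
    "total_fatigue",
    "detect_fatigue_point",
    "write_detection_json",
    "write_detection_csv",
]

# Loose enough to admit the printed equal-weight triple (0.33, 0.33, 0.33);
# M_total divides by the present-weight sum, so the overall scale cancels.
_WEIGHT_TOL = 0.02


@dataclass(frozen=True)
class ScoreParams:
    """Scoring and detection parameters.

    alpha   : fatigue interval index in (0, 1]
    weights : (W1, W2, W3) for elbow, trunk, interval; non-negative, sum 1
    threshold : T on the percent scale [0, 100] (or [0, 1] with raw_scale)
    persistence : number of consecutive pitches that must reach T
    search_window : "full" searches the whole game; "alpha" only the
        non-fatigue prefix of floor(alpha * N) pitches
    raw_scale : report M_total in [0, 1] instead of percent
    """

    alpha: float = 0.7
    weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    threshold: float = 50.0
    persistence: int = 1
    search_window: str = "full"
    raw_scale: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if not 0.0 < self.alpha <= 1.0:
            raise ParameterError(f"alpha {self.alpha} outside (0, 1]")
        if len(self.weights) != 3 or any(w < 0 for w in self.weights):
            raise ParameterError(f"weights {self.weights} must be 3 non-negatives")
        if abs(sum(self.weights) - 1.0) > _WEIGHT_TOL:
            raise ParameterError(f"weights {self.weights} must sum to 1")
        limit = 1.0 if self.raw_scale else 100.0
        if not 0.0 <= self.threshold <= limit:
            raise ParameterError(
                f"threshold {self.threshold} outside [0, {limit:g}]"
            )
        if self.persistence < 1:
            raise ParameterError(f"persistence {self.persistence} must be >= 1")
        if self.search_window not in ("full", "alpha"):
            raise ParameterError(f"search window {self.search_window!r}")

    @property
    def scale(self) -> float:
        return 1.0 if self.raw_scale else 100.0

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "weights": list(self.weights),
            "threshold": self.threshold,
            "persistence": self.persistence,
            "search_window": self.search_window,
            "raw_scale": self.raw_scale,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ScoreParams":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in payload.items() if k in known}
        if "weights" in kwargs:
            kwargs["weights"] = tuple(kwargs["weights"])
        return cls(**kwargs)


@dataclass(frozen=True)
class DetectionResult:
    """Fatigue point and audit series for one game."""

    game_id: str
    fatigue_point: int | None  # R, 1-based pitch index of first crossing
    m_series: tuple[float | None, ...]
    scores: tuple[PitchScore, ...] = field(default_factory=tuple)

    @property
    def detected(self) -> bool:
        return self.fatigue_point is not None


def total_fatigue(score: PitchScore, params: ScoreParams) -> float | None:
    """Weighted total fatigue index for one pitch, on the percent scale.

    Missing features are excluded and the remaining weights renormalized so
    the index keeps its [0, scale] range; ``None`` when every feature (or all
    non-zero weight) is missing.
    """
    pairs = [
        (a, w)
        for a, w in zip(score.values(), params.weights)
        if a is not None
    ]
    if not pairs:
        return None
    weight_sum = sum(w for _, w in pairs)
    if weight_sum == 0.0:
        return None
    return params.scale * sum(a * w for a, w in pairs) / weight_sum


def detect_fatigue_point(
    session: GameSession,
    bounds: FeatureBounds,
    params: ScoreParams,
    degenerate: str = "error",
) -> DetectionResult:
    """Locate the first pitch whose M_total reaches the threshold T.

    With ``persistence > 1`` the crossing must hold for that many consecutive
    pitches (a missing M_total breaks the run).  R is the index where the run
    starts, or ``None`` when no pitch qualifies.
    """
    scores = score_session(session, bounds, degenerate)
    m_series = tuple(total_fatigue(s, params) for s in scores)
    scores = tuple(
        replace(s, m_total=m) for s, m in zip(scores, m_series)
    )

    if params.search_window == "alpha":
        limit, _ = split_intervals(session.n_pitches, params.alpha)
    else:
        limit = session.n_pitches

    fatigue_point = None
    run = 0
    for i, m in enumerate(m_series, start=1):
        if m is not None and m >= params.threshold:
            run += 1
            if run >= params.persistence:
                start = i - params.persistence + 1
                if start <= limit:
                    fatigue_point = start
                    break
        else:
            run = 0
    return DetectionResult(
        game_id=session.game_id,
        fatigue_point=fatigue_point,
        m_series=m_series,
        scores=scores,
    )


def write_detection_json(
    results: Sequence[DetectionResult], path: str | Path
) -> None:
    payload = {
        r.game_id: {
            "fatigue_point": r.fatigue_point,
            "m_series": list(r.m_series),
        }
        for r in results
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_detection_csv(
    results: Sequence[DetectionResult], path: str | Path
) -> None:
    rows = []
    for r in results:
        for score, m in zip(r.scores, r.m_series):
            rows.append(
                {
                    "game_id": r.game_id,
                    "pitch_index": score.pitch_index,
                    "A1": score.a_elbow,
                    "A2": score.a_trunk,
                    "A3": score.a_interval,
                    "M_total": m,
                    "crossed_flag": bool(
                        r.fatigue_point is not None
                        and score.pitch_index >= r.fatigue_point
                    ),
                    "R": r.fatigue_point,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
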