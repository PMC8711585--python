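"""Leave-one-game-out evaluation, parameter grid search, and a classifier hook.

Each game serves once as the held-out fold.  Every training game gets its own
alpha-split bounds and detected fatigue point R_i; the training fatigue points
are pooled into F_P (their plain mean by default) and scored against the
held-out game's target pitch ``N_i * alpha``:

    A_f = 1 - |F_P - N_i * alpha| / N_i

The final accuracy is the average of the per-fold A_f values.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .detect import ScoreParams, detect_fatigue_point
from .errors import (
    DegenerateBoundsError,
    InsufficientDataError,
    NoDetectionError,
    ParameterError,
)
from .pose_io import GameSession
from .quantify import interval_bounds, score_session, split_intervals

__all__ = [
    "FoldRecord",
    "CVReport",
    "GridResult",
    "pooled_fatigue_point",
    "fold_accuracy",
    "cross_validate",
    "grid_search",
    "fit_fatigue_classifier",
    "train_fatigue_classifier",
    "save_classifier",
    "load_classifier",
]


@dataclass(frozen=True)
class FoldRecord:
    """One leave-one-game-out fold."""

    held_out: str
    r_by_game: dict[str, int | None]
    pooled_point: float | None  # F_P
    n_held_out: int
    accuracy: float | None  # A_f, None when the fold failed
    error: str | None = None


@dataclass(frozen=True)
class CVReport:
    """Cross-validation outcome across all folds."""

    params: ScoreParams
    folds: tuple[FoldRecord, ...]
    mean_accuracy: float
    pooling: str
    clamp: bool

    @property
    def n_games(self) -> int:
        return len(self.folds)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "pooling": self.pooling,
            "clamp": self.clamp,
            "mean_accuracy": self.mean_accuracy,
            "folds": [
                {
                    "held_out": f.held_out,
                    "r_by_game": f.r_by_game,
                    "pooled_point": f.pooled_point,
                    "n_held_out": f.n_held_out,
                    "accuracy": f.accuracy,
                    "error": f.error,
                }
                for f in self.folds
            ],
        }


@dataclass(frozen=True)
class GridResult:
    """Grid-search outcome: every evaluated tuple plus the winner."""

    entries: tuple[tuple[ScoreParams, float], ...]
    best: ScoreParams
    best_accuracy: float

    def to_dict(self) -> dict:
        return {
            "entries": [
                {"params": p.to_dict(), "mean_accuracy": acc}
                for p, acc in self.entries
            ],
            "best": self.best.to_dict(),
            "best_accuracy": self.best_accuracy,
        }


def pooled_fatigue_point(
    fatigue_points: Sequence[int],
    mode: str = "absolute",
    n_pitches: Sequence[int] | None = None,
    n_val: int | None = None,
) -> float:
    """Pool training-game fatigue points into F_P.

    ``absolute`` is the plain mean of the R_i.  ``normalized`` averages the
    fractions R_i / N_i and rescales by the held-out game's pitch count
    ``n_val`` (rounded to a pitch index).
    """
    if not fatigue_points:
        raise NoDetectionError("no training game produced a fatigue point")
    if mode == "absolute":
        return float(np.mean(fatigue_points))
    if mode == "normalized":
        if n_pitches is None or n_val is None:
            raise ParameterError("normalized pooling needs n_pitches and n_val")
        if len(n_pitches) != len(fatigue_points):
            raise ParameterError("n_pitches must align with fatigue_points")
        fractions = [r / n for r, n in zip(fatigue_points, n_pitches)]
        return float(round(float(np.mean(fractions)) * n_val))
    raise ParameterError(f"pooling mode {mode!r}")


def fold_accuracy(
    pooled_point: float, n_pitches: int, alpha: float, clamp: bool = False
) -> float:
    """Accuracy A_f = 1 - |F_P - N*alpha| / N (raw value may be negative)."""
    if n_pitches < 1:
        raise ParameterError(f"n_pitches {n_pitches} must be >= 1")
    value = 1.0 - abs(pooled_point - n_pitches * alpha) / n_pitches
    return max(0.0, value) if clamp else value


def _detect_all(
    sessions: Sequence[GameSession],
    params: ScoreParams,
    degenerate: str,
) -> tuple[dict[str, int | None], dict[str, str]]:
    """Per-game fatigue points using each game's own alpha-split bounds."""
    points: dict[str, int | None] = {}
    failures: dict[str, str] = {}
    for session in sessions:
        try:
            bounds = interval_bounds(session, params.alpha)
            result = detect_fatigue_point(session, bounds, params, degenerate)
            points[session.game_id] = result.fatigue_point
        except (InsufficientDataError, DegenerateBoundsError) as exc:
            points[session.game_id] = None
            failures[session.game_id] = str(exc)
    return points, failures


def cross_validate(
    sessions: Sequence[GameSession],
    params: ScoreParams,
    pooling: str = "absolute",
    clamp: bool = False,
    degenerate: str = "error",
) -> CVReport:
    """Leave-one-game-out cross-validation of the detection pipeline.

    Bounds are estimated per training game (the held-out game contributes
    only its pitch count — no feature leakage).  Games whose bounds fail or
    that never cross the threshold contribute no R_i; a fold with no usable
    training detection is recorded as failed, and the report errors only when
    every fold fails.
    """
    if len(sessions) < 2:
        raise ParameterError("cross-validation needs at least 2 games")
    ids = [s.game_id for s in sessions]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate game ids in {ids}")

    points, failures = _detect_all(sessions, params, degenerate)
    n_by_game = {s.game_id: s.n_pitches for s in sessions}

    folds = []
    for held_out in sessions:
        train_ids = [g for g in ids if g != held_out.game_id]
        r_by_game = {g: points[g] for g in train_ids}
        usable = [(g, r) for g, r in r_by_game.items() if r is not None]
        if not usable:
            folds.append(
                FoldRecord(
                    held_out=held_out.game_id,
                    r_by_game=r_by_game,
                    pooled_point=None,
                    n_held_out=held_out.n_pitches,
                    accuracy=None,
                    error="no training game produced a fatigue point",
                )
            )
            continue
        pooled = pooled_fatigue_point(
            [r for _, r in usable],
            mode=pooling,
            n_pitches=[n_by_game[g] for g, _ in usable],
            n_val=held_out.n_pitches,
        )
        folds.append(
            FoldRecord(
                held_out=held_out.game_id,
                r_by_game=r_by_game,
                pooled_point=pooled,
                n_held_out=held_out.n_pitches,
                accuracy=fold_accuracy(
                    pooled, held_out.n_pitches, params.alpha, clamp
                ),
                error="; ".join(
                    f"{g}: {failures[g]}" for g in train_ids if g in failures
                ) or None,
            )
        )

    accuracies = [f.accuracy for f in folds if f.accuracy is not None]
    if not accuracies:
        raise NoDetectionError("every cross-validation fold failed")
    return CVReport(
        params=params,
        folds=tuple(folds),
        mean_accuracy=float(np.mean(accuracies)),
        pooling=pooling,
        clamp=clamp,
    )


def grid_search(
    sessions: Sequence[GameSession],
    alphas: Sequence[float],
    weight_triples: Sequence[Sequence[float]],
    thresholds: Sequence[float],
    pooling: str = "absolute",
    clamp: bool = False,
    degenerate: str = "error",
    base_params: ScoreParams | None = None,
) -> GridResult:
    """Evaluate cross_validate over the (alpha, W, T) product grid.

    The winner maximizes mean accuracy; ties break deterministically by
    larger alpha, then lower threshold, then lexicographically larger weight
    triple.
    """
    if not (alphas and weight_triples and thresholds):
        raise ParameterError("grid must be non-empty in every dimension")
    base = base_params or ScoreParams()
    entries = []
    for alpha, weights, threshold in itertools.product(
        alphas, weight_triples, thresholds
    ):
        params = ScoreParams(
            alpha=alpha,
            weights=tuple(weights),
            threshold=threshold,
            persistence=base.persistence,
            search_window=base.search_window,
            raw_scale=base.raw_scale,
        )
        report = cross_validate(sessions, params, pooling, clamp, degenerate)
        entries.append((params, report.mean_accuracy))

    def rank(entry: tuple[ScoreParams, float]):
        params, accuracy = entry
        return (accuracy, params.alpha, -params.threshold, params.weights)

    best_params, best_accuracy = max(entries, key=rank)
    return GridResult(
        entries=tuple(entries), best=best_params, best_accuracy=best_accuracy
    )


def fit_fatigue_classifier(
    features: np.ndarray, labels: np.ndarray, random_state: int = 0
):
    """Fit a binary margin classifier (SVC) on feature rows and 0/1 labels."""
    from sklearn.svm import SVC

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ParameterError("classifier training needs both interval classes")
    model = SVC(kernel="rbf", random_state=random_state)
    model.fit(features, labels)
    return model


def train_fatigue_classifier(
    sessions: Sequence[GameSession],
    alpha: float,
    random_state: int = 0,
):
    """Fit a binary margin classifier on (A1, A2, A3) fatigue-value triples.

    Labels come from each session's alpha-split interval membership; pitches
    with any missing fatigue value are dropped.  Returns a fitted
    scikit-learn SVC.
    """
    features, labels = [], []
    for session in sessions:
        n_nf, _ = split_intervals(session.n_pitches, alpha)
        bounds = interval_bounds(session, alpha)
        for score in score_session(session, bounds):
            triple = score.values()
            if any(v is None for v in triple):
                continue
            features.append(triple)
            labels.append(int(score.pitch_index > n_nf))
    return fit_fatigue_classifier(features, labels, random_state)


def save_classifier(model, path: str | Path) -> None:
    joblib.dump(model, path)


def load_classifier(path: str | Path):
    return joblib.load(path)


def write_cv_json(report: CVReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))


def write_grid_json(result: GridResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
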