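import numpy as np
import pytest

from pitchfatigue.pose_io import GameSession, PitchObservation
from pitchfatigue.quantify import FeatureBounds, FeatureStats
from pitchfatigue.simulate import SimConfig, simulate_games


def make_session(c, k, t, game_id="g1"):
    """Build a session from raw feature lists (None = missing)."""
    n = len(c)
    assert len(k) == n and len(t) == n
    return GameSession(
        game_id=game_id,
        observations=tuple(
            PitchObservation(
                game_id=game_id, pitch_index=i + 1, c=c[i], k=k[i], t=t[i]
            )
            for i in range(n)
        ),
    )


def make_stats(x, y):
    """FeatureStats with prescribed knots (regime stats backfilled)."""
    return FeatureStats(nf_mean=x, nf_sd=0.0, f_mean=y, f_sd=0.0, x=x, y=y)


def make_bounds(elbow=(100.0, 115.0), trunk=(95.0, 80.0), interval=(20.0, 28.0)):
    """Valid-orientation bounds with prescribed (x, y) knots per feature."""
    return FeatureBounds(
        elbow=make_stats(*elbow),
        trunk=make_stats(*trunk),
        interval=make_stats(*interval),
    )


def random_valid_bounds(rng):
    """Random bounds with correct orientation for every feature."""
    x1 = rng.uniform(60, 120)
    x2 = rng.uniform(60, 120)
    x3 = rng.uniform(10, 30)
    return make_bounds(
        elbow=(x1, x1 + rng.uniform(1, 40)),
        trunk=(x2, x2 - rng.uniform(1, 40)),
        interval=(x3, x3 + rng.uniform(0.5, 15)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sim_config():
    return SimConfig(n_pitches=100, n_games=7, onset_fraction=0.7, seed=42)


@pytest.fixture
def seven_games(sim_config):
    sessions, truths = simulate_games(sim_config)
    return sessions, truths
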