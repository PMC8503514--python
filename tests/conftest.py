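import numpy as np
import pytest

from liveplay import (
    DetectorParams,
    SimulationParams,
    simulate_match,
)


@pytest.fixture(scope="session")
def default_sim_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def small_sim_params():
    """A few minutes of match, 6 players: fast but structurally complete."""
    return SimulationParams(
        roster_size=6, quarter_span_s=120, quarter_break_s=20, half_time_s=60
    )


@pytest.fixture(scope="session")
def simulated_match(default_sim_params):
    """One full-length synthetic match with ground truth (seed 42)."""
    schedule, series, truth = simulate_match(default_sim_params, seed=42)
    return schedule, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def default_params():
    return DetectorParams()


def random_mask(rng, n=None):
    """Random boolean mask with realistic run structure."""
    if n is None:
        n = int(rng.integers(5, 400))
    return rng.random(n) < rng.uniform(0.2, 0.8)
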