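import numpy as np
import pytest

from dyadmove import (
    MovementKernel,
    NoiseConfig,
    ScenarioConfig,
    Trajectory,
    make_perlin_landscape,
    simulate_pair,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def perlin_grid():
    return make_perlin_landscape(100, 100, 1.0, NoiseConfig(seed=3))


@pytest.fixture(scope="session")
def pair_d():
    """One simulated scenario-D pair (mutual attraction)."""
    return simulate_pair(ScenarioConfig(scenario="D", seed=21))


@pytest.fixture(scope="session")
def pair_crw():
    """One pair of independent correlated random walks."""
    from dyadmove import simulate_crw_pair

    return simulate_crw_pair(seed=22)


def walk_trajectory(rng, n_steps=100, start=(50.0, 50.0), individual_id="w"):
    """Small synthetic CRW used by unit tests (kernel defaults)."""
    k = MovementKernel()
    heading = rng.uniform(-np.pi, np.pi)
    x, y = [start[0]], [start[1]]
    for _ in range(n_steps):
        heading += rng.vonmises(0.0, k.kappa)
        step = rng.gamma(k.gamma_shape, k.gamma_scale)
        x.append(x[-1] + step * np.cos(heading))
        y.append(y[-1] + step * np.sin(heading))
    return Trajectory(individual_id, np.arange(n_steps + 1), np.array(x), np.array(y))
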