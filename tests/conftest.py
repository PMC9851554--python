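"""Shared fixtures: study-default parameters and a small solved MDP."""

from __future__ import annotations

import numpy as np
import pytest

from pendulum_entropy.controllers import (
    GridSpec,
    NoiseParams,
    build_mdp,
    run_grid,
    value_iteration,
)
from pendulum_entropy.dynamics import PendulumParams


@pytest.fixture(scope="session")
def params():
    return PendulumParams()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(angle_bins=64, speed_bins=64)


@pytest.fixture(scope="session")
def solved_l05(small_grid):
    """Optimal policy for the half-metre pendulum on the small grid."""
    p = PendulumParams(length=0.5)
    mdp = build_mdp(p, small_grid)
    vi = value_iteration(mdp)
    assert vi.converged
    return p, mdp, vi


@pytest.fixture(scope="session")
def mini_study(small_grid):
    """A reduced noiseless controller family: 2 lengths x 6 levels."""
    return run_grid(
        lengths=(0.4, 0.8),
        n_levels=6,
        noise=NoiseParams(),
        grid=small_grid,
        n_steps=3000,
        base_seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
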