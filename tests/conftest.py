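"""Shared fixtures: trajectories reused across test modules.

Everything here is generated at test time; session scope keeps the more
expensive simulations to one run each.
"""

import numpy as np
import pytest

import burstglide as bg


@pytest.fixture(scope="session")
def lin_osc():
    """Single fish, linear drag, c=0.95: bursting limit cycle."""
    return bg.simulate(
        (0.0, 0.0),
        bg.ModelParams.linear_defaults(c=0.95),
        settings=bg.SimSettings(t_end=500.0, transient=250.0),
    )


@pytest.fixture(scope="session")
def lin_eq():
    """Single fish, linear drag, c=0.9: converges to the stable equilibrium."""
    return bg.simulate(
        (0.0, 0.0),
        bg.ModelParams.linear_defaults(c=0.9),
        settings=bg.SimSettings(t_end=500.0, transient=250.0),
    )


@pytest.fixture(scope="session")
def pair_d02():
    """Coupled pair in the periodic leadership-switching regime (d=0.02)."""
    return bg.simulate(
        (0.0, 0.0, 5.0, 0.0, 0.0, 0.0),
        bg.ModelParams.linear_defaults(c=0.9255),
        bg.CouplingParams(d=0.02),
        bg.regimes.SWEEP_SETTINGS,
    )


@pytest.fixture(scope="session")
def pair_d05():
    """Coupled pair in the leader-follower regime (d=0.05)."""
    return bg.simulate(
        (0.0, 0.0, 5.0, 0.0, 0.0, 0.0),
        bg.ModelParams.linear_defaults(c=0.9255),
        bg.CouplingParams(d=0.05),
        bg.SimSettings(t_end=1000.0, transient=250.0),
    )


@pytest.fixture(scope="session")
def pair_d07():
    """Coupled pair in the leaderless turn-taking regime (d=0.07)."""
    return bg.simulate(
        (0.0, 0.0, 5.0, 0.0, 0.0, 0.0),
        bg.ModelParams.linear_defaults(c=0.9255),
        bg.CouplingParams(d=0.07),
        bg.SimSettings(t_end=1000.0, transient=250.0),
    )


def synthetic_pair_trajectory(times, separation, speed=0.3):
    """Build a pair Trajectory whose x1 - x2 equals ``separation`` exactly.

    Used to test leadership/peak utilities against closed-form signals.
    """
    n = len(times)
    states = np.zeros((n, 6))
    states[:, 1] = speed  # v1
    states[:, 4] = speed  # v2
    states[:, 2] = separation  # x1
    states[:, 5] = 0.0  # x2
    return bg.Trajectory(
        np.asarray(times, float),
        states,
        bg.ModelParams.linear_defaults(),
        bg.CouplingParams(),
        0.0,
    )
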