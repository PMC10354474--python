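"""Deterministic numerical integration producing uniformly sampled trajectories.

The main entry point is :func:`simulate`, a thin wrapper around scipy's
adaptive explicit Runge-Kutta solvers sampled on a fixed output grid.
:func:`euler_oracle` is a deliberately independent forward-Euler reference
used by the test suite to cross-check the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams, CouplingParams
from .model import rhs_single, rhs_pair

__all__ = ["SimSettings", "Trajectory", "simulate", "euler_oracle"]

SINGLE_COLUMNS = ("b1", "v1")
PAIR_COLUMNS = ("b1", "v1", "x1", "b2", "v2", "x2")


@dataclass(frozen=True)
class SimSettings:
    """Integration settings.

    t_end : total simulated time (s).  dt_out : output sampling interval (s).
    rtol/atol : local error tolerances of the adaptive solver.  transient :
    initial span (s) that analyses discard.  method : any explicit solve_ivp
    method ("RK45" is Dormand-Prince 5(4)).  seed is carried along for
    protocols that randomize initial conditions.
    """

    t_end: float = 1000.0
    dt_out: float = 0.05
    rtol: float = 1e-8
    atol: float = 1e-10
    transient: float = 250.0
    method: str = "RK45"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.t_end > self.transient >= 0:
            raise ValueError(f"need t_end > transient >= 0, got {self.t_end}, {self.transient}")
        if self.dt_out <= 0:
            raise ValueError("dt_out must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "SimSettings":
        return replace(self, **kw)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled time series of model states.

    ``states`` has one row per time point; columns are (b, v) for a single
    fish and (b1, v1, x1, b2, v2, x2) for a pair.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParams
    coupling: CouplingParams | None = None
    transient: float = 0.0

    @property
    def kind(self) -> str:
        return "pair" if self.states.shape[1] == 6 else "single"

    @property
    def columns(self) -> tuple[str, ...]:
        return PAIR_COLUMNS if self.kind == "pair" else SINGLE_COLUMNS

    def channel(self, name: str) -> np.ndarray:
        if name == "separation":
            return self.separation()
        return self.states[:, self.columns.index(name)]

    def speed(self, fish: int = 0) -> np.ndarray:
        return self.states[:, 1 if self.kind == "single" else (1, 4)[fish]]

    def separation(self) -> np.ndarray:
        """Distance difference x1 - x2 (cm); pair trajectories only."""
        if self.kind != "pair":
            raise ValueError("separation is defined for pair trajectories only")
        return self.states[:, 2] - self.states[:, 5]

    def derivatives(self) -> np.ndarray:
        """Model right-hand side evaluated at every sample (analytic, not
        finite-differenced).  Vectorized over time."""
        if self.kind == "single":
            return np.asarray(rhs_single(self.states.T, self.params)).T
        return np.asarray(rhs_pair(self.states.T, self.params, self.coupling)).T

    def post_transient(self, transient: float | None = None) -> "Trajectory":
        """View of the trajectory from ``transient`` (default: the recorded
        one) to the end."""
        cut = self.transient if transient is None else transient
        m = self.times >= cut
        return Trajectory(self.times[m], self.states[m], self.params, self.coupling, 0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, **{c: self.states[:, i] for i, c in enumerate(self.columns)}})

    def validate(self) -> None:
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")
        speeds = self.states[:, 1::3] if self.kind == "pair" else self.states[:, 1:2]
        if speeds.min() < -1e-6:
            raise ValueError(f"negative speed {speeds.min()} in trajectory")


def _output_grid(settings: SimSettings) -> np.ndarray:
    n = int(math.floor(settings.t_end / settings.dt_out + 1e-9))
    return np.arange(n + 1) * settings.dt_out


def _scalar_rhs_single(p: ModelParams):
    """Scalar closure for the solver hot loop (same arithmetic as rhs_single)."""
    a, k, c, z1, b0 = p.a, p.k, p.c, p.z1, p.b0
    quad = p.drag == "quadratic"

    def fun(t, y):
        b, v = y
        g = a * (math.atan(z1 * (b - b0)) / math.pi + 0.5)
        dv = g * g - (k * v) ** 2 if quad else g - k * v
        return (b - b * b * b / 3.0 + c - v, dv)

    return fun


def _scalar_rhs_pair(p: ModelParams, cp: CouplingParams):
    a, k, c, z1, b0 = p.a, p.k, p.c, p.z1, p.b0
    d, z2, x0, gam = cp.d, cp.z2, cp.x0, cp.gamma
    quad = p.drag == "quadratic"

    def f(x_rel):
        e = -z2 * (x_rel - x0)
        e = 700.0 if e > 700.0 else (-700.0 if e < -700.0 else e)
        return d / (1.0 + math.exp(e))

    def fun(t, y):
        b1, v1, x1, b2, v2, x2 = y
        g1 = a * (math.atan(z1 * (b1 - b0)) / math.pi + 0.5)
        g2 = a * (math.atan(z1 * (b2 - b0)) / math.pi + 0.5)
        if quad:
            dv1 = g1 * g1 - (k * v1) ** 2
            dv2 = g2 * g2 - (k * v2) ** 2
        else:
            dv1 = g1 - k * v1
            dv2 = g2 - k * v2
        return (
            b1 - b1 * b1 * b1 / 3.0 + c + f(x2 - x1) - v1,
            dv1,
            gam * v1,
            b2 - b2 * b2 * b2 / 3.0 + c + f(x1 - x2) - v2,
            dv2,
            gam * v2,
        )

    return fun


def simulate(
    initial: Sequence[float],
    p: ModelParams,
    cp: CouplingParams | None = None,
    settings: SimSettings = SimSettings(),
) -> Trajectory:
    """Integrate the single- or pair-model ODEs.

    ``initial`` is (b, v) for one fish or (b1, v1, x1, b2, v2, x2) for a
    coupled pair (``cp`` required).  Output is sampled at ``settings.dt_out``;
    the result is deterministic given identical inputs and settings.
    """
    y0 = np.asarray(initial, float)
    if y0.shape == (2,):
        fun = _scalar_rhs_single(p)
        cp_used = None
    elif y0.shape == (6,):
        if cp is None:
            raise ValueError("coupling parameters are required for a pair simulation")
        fun = _scalar_rhs_pair(p, cp)
        cp_used = cp
    else:
        raise ValueError(f"initial state must have 2 or 6 components, got {y0.shape}")

    t_eval = _output_grid(settings)
    sol = solve_ivp(
        fun,
        (0.0, settings.t_end),
        y0,
        method=settings.method,
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}")
    traj = Trajectory(sol.t, sol.y.T, p, cp_used, settings.transient)
    traj.validate()
    return traj


def euler_oracle(
    initial: Sequence[float],
    p: ModelParams,
    cp: CouplingParams | None = None,
    dt: float = 1e-4,
    n_steps: int = 0,
) -> Trajectory:
    """Forward-Euler reference integrator (verification oracle).

    First-order accurate; intended for short horizons at small dt where the
    adaptive solver must agree within O(dt).  A 0-step call returns just the
    initial state.
    """
    y = list(map(float, initial))
    is_pair = len(y) == 6
    if is_pair and cp is None:
        raise ValueError("coupling parameters are required for a pair simulation")
    fun = _scalar_rhs_pair(p, cp) if is_pair else _scalar_rhs_single(p)
    out = np.empty((n_steps + 1, len(y)))
    out[0] = y
    for i in range(n_steps):
        dy = fun(0.0, y)
        y = [y[j] + dt * dy[j] for j in range(len(y))]
        out[i + 1] = y
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times, out, p, cp if is_pair else None, 0.0)
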