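"""Right-hand sides, nullclines, equilibria and linear stability.

The single fish is a two-variable slow-fast oscillator in the FitzHugh-Nagumo
family: the burst potential b plays the role of the membrane potential and the
swimming speed v replaces the recovery variable,

    db/dt = b - b^3/3 + c - v
    dv/dt = g(b) - k v              (linear drag)
    dv/dt = g(b)^2 - (k v)^2        (quadratic drag)

with the arctangent propulsion sigmoid g(b) = a (arctan(z1 (b - b0))/pi + 1/2).
Two fish are coupled through a logistic visual response f of the signed
distance to the neighbour, acting as an extra boost on the tonic input c.
"""

from __future__ import annotations

import math
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, CouplingParams, LINEAR

__all__ = [
    "SingleState",
    "PairState",
    "propulsion",
    "propulsion_deriv",
    "response",
    "rhs_single",
    "rhs_pair",
    "nullclines",
    "find_equilibria",
    "find_equilibrium",
    "jacobian",
    "jacobian_eigen",
    "locate_oscillation_onset",
]

_EXP_CLAMP = 700.0  # |exponent| cap; preserves the logistic limits in float64


class SingleState(NamedTuple):
    """Instantaneous state of one fish: burst potential and speed."""

    b: float
    v: float


class PairState(NamedTuple):
    """Instantaneous state of a coupled pair (positions in cm)."""

    b1: float
    v1: float
    x1: float
    b2: float
    v2: float
    x2: float


def propulsion(b, p: ModelParams):
    """Propulsive force g(b) = a (arctan(z1 (b - b0))/pi + 1/2).

    Strictly increasing in b, bounded in (0, a).  Accepts scalars or arrays.
    """
    return p.a * (np.arctan(p.z1 * (np.asarray(b, float) - p.b0)) / math.pi + 0.5)


def propulsion_deriv(b, p: ModelParams):
    """dg/db = a z1 / (pi (1 + z1^2 (b - b0)^2))."""
    u = p.z1 * (np.asarray(b, float) - p.b0)
    return p.a * p.z1 / (math.pi * (1.0 + u * u))


def response(x_rel, cp: CouplingParams):
    """Visual-response boost f(x_rel) = d / (1 + exp(-z2 (x_rel - x0))).

    ``x_rel`` is the neighbour's position minus one's own (cm).  The exponent
    is clamped so the function saturates exactly instead of overflowing.
    """
    e = -cp.z2 * (np.asarray(x_rel, float) - cp.x0)
    e = np.clip(e, -_EXP_CLAMP, _EXP_CLAMP)
    return cp.d / (1.0 + np.exp(e))


def rhs_single(state: Sequence[float], p: ModelParams) -> np.ndarray:
    """Time derivative (db/dt, dv/dt) of the single-fish model."""
    b, v = state
    g = propulsion(b, p)
    if p.drag == LINEAR:
        dv = g - p.k * v
    else:
        dv = g * g - (p.k * v) ** 2
    return np.array([b - b**3 / 3.0 + p.c - v, dv])


def rhs_pair(state: Sequence[float], p: ModelParams, cp: CouplingParams) -> np.ndarray:
    """Time derivative of the pair state (b1, v1, x1, b2, v2, x2).

    Each fish's internal state receives c + f(other - self); with d=0 the two
    fish are exactly decoupled copies of the single-fish model.  Positions
    obey dx_i/dt = gamma v_i.
    """
    b1, v1, x1, b2, v2, x2 = state
    g1 = propulsion(b1, p)
    g2 = propulsion(b2, p)
    if p.drag == LINEAR:
        dv1 = g1 - p.k * v1
        dv2 = g2 - p.k * v2
    else:
        dv1 = g1 * g1 - (p.k * v1) ** 2
        dv2 = g2 * g2 - (p.k * v2) ** 2
    return np.array(
        [
            b1 - b1**3 / 3.0 + p.c + response(x2 - x1, cp) - v1,
            dv1,
            cp.gamma * v1,
            b2 - b2**3 / 3.0 + p.c + response(x1 - x2, cp) - v2,
            dv2,
            cp.gamma * v2,
        ]
    )


def nullclines(p: ModelParams) -> tuple[Callable, Callable]:
    """Return the two nullclines as callables v(b).

    The b-nullcline is v = b - b^3/3 + c; the v-nullcline is v = g(b)/k and is
    identical for linear and quadratic drag (restricted to v >= 0, since the
    quadratic balance g^2 = (kv)^2 has the same non-negative solution).
    """

    def b_nullcline(b):
        b = np.asarray(b, float)
        return b - b**3 / 3.0 + p.c

    def v_nullcline(b):
        return propulsion(b, p) / p.k

    return b_nullcline, v_nullcline


def _equilibrium_residual(b: float, p: ModelParams, effective_c: float) -> float:
    return b - b**3 / 3.0 + effective_c - propulsion(b, p) / p.k


def find_equilibria(
    p: ModelParams,
    effective_c: float | None = None,
    bracket: tuple[float, float] = (-3.0, 3.0),
    n_scan: int = 600,
) -> list[SingleState]:
    """All equilibria (b*, v*) of the single-fish model on the bracket.

    Roots of b - b^3/3 + c_eff - g(b)/k are located by scanning ``n_scan``
    subintervals for sign changes and polishing each with Brent's method;
    v* = g(b*)/k.  Returns an empty list if no sign change is found.
    """
    c_eff = p.c if effective_c is None else effective_c
    grid = np.linspace(bracket[0], bracket[1], n_scan + 1)
    vals = [_equilibrium_residual(b, p, c_eff) for b in grid]
    roots: list[float] = []
    for i in range(n_scan):
        lo, hi = vals[i], vals[i + 1]
        if lo == 0.0:
            roots.append(grid[i])
        elif lo * hi < 0:
            roots.append(
                brentq(_equilibrium_residual, grid[i], grid[i + 1], args=(p, c_eff), xtol=1e-14)
            )
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    out = []
    for b in roots:
        assert abs(_equilibrium_residual(b, p, c_eff)) < 1e-10
        out.append(SingleState(b=float(b), v=float(propulsion(b, p) / p.k)))
    return out


def find_equilibrium(p: ModelParams, effective_c: float | None = None) -> SingleState:
    """The unique equilibrium on [-3, 3]; raises if there are zero or several."""
    eqs = find_equilibria(p, effective_c)
    if len(eqs) != 1:
        raise ValueError(f"expected a unique equilibrium, found {len(eqs)}: {eqs}")
    return eqs[0]


def jacobian(p: ModelParams, eq: Sequence[float]) -> np.ndarray:
    """Jacobian of the single-fish vector field at an equilibrium.

    Linear drag:   [[1 - b^2, -1], [g'(b), -k]].
    Quadratic drag: the speed row becomes [2 g(b) g'(b), -2 k^2 v].
    """
    b, v = eq
    res = rhs_single((b, v), p)
    if np.max(np.abs(res)) > 1e-6:
        raise ValueError(f"({b}, {v}) is not an equilibrium (residual {res})")
    gp = propulsion_deriv(b, p)
    if p.drag == LINEAR:
        row = [gp, -p.k]
    else:
        row = [2.0 * propulsion(b, p) * gp, -2.0 * p.k**2 * v]
    return np.array([[1.0 - b * b, -1.0], row])


def jacobian_eigen(p: ModelParams, eq: Sequence[float]):
    """(trace, determinant, eigenvalues) of the Jacobian at an equilibrium."""
    J = jacobian(p, eq)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    eig = np.linalg.eigvals(J)
    # eigenvalues must be consistent with trace/det
    assert abs(eig.sum().real - tr) < 1e-10 and abs(np.prod(eig).real - det) < 1e-8
    return tr, det, eig


def _oscillates(
    p: ModelParams,
    amplitude_threshold: float,
    t_end: float,
    transient: float,
    initial: Sequence[float],
) -> bool:
    from .integrate import SimSettings, simulate  # local import to avoid a cycle

    traj = simulate(initial, p, settings=SimSettings(t_end=t_end, transient=transient))
    v = traj.post_transient().states[:, 1]
    return float(v.max() - v.min()) > amplitude_threshold


def locate_oscillation_onset(
    p: ModelParams,
    c_lo: float,
    c_hi: float,
    criterion: str = "simulation",
    resolution: float = 1e-3,
    amplitude_threshold: float = 0.05,
    t_end: float = 500.0,
    transient: float = 250.0,
    initial: Sequence[float] = (0.0, 0.0),
) -> float:
    """Locate the tonic-input value c* where oscillation sets in, by bisection.

    criterion="simulation" (default): integrate from ``initial`` for ``t_end``
    seconds, discard ``transient``, and declare oscillation when the remaining
    speed amplitude (max - min) exceeds ``amplitude_threshold``.  This is the
    operational analogue of sweeping c upward from rest, and is robust to the
    sub-critical structure near the bifurcation.

    criterion="linearization": bisect on the sign of the largest eigenvalue
    real part of the Jacobian at the equilibrium.

    Raises ValueError if both endpoints classify identically.
    """
    if not c_lo < c_hi:
        raise ValueError("need c_lo < c_hi")

    if criterion == "simulation":
        def osc(c):
            return _oscillates(p.with_c(c), amplitude_threshold, t_end, transient, initial)
    elif criterion == "linearization":
        # oscillation <=> every equilibrium is linearly unstable (near the
        # fold there can be three equilibria; a single stable one quenches
        # the oscillation)
        def osc(c):
            eqs = find_equilibria(p.with_c(c))
            if not eqs:
                raise ValueError(f"no equilibrium found at c={c}")
            stab = [float(np.max(jacobian_eigen(p.with_c(c), eq)[2].real)) for eq in eqs]
            return all(s > 0 for s in stab)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    lo_osc, hi_osc = osc(c_lo), osc(c_hi)
    if lo_osc == hi_osc:
        raise ValueError(
            f"no onset bracketed in [{c_lo}, {c_hi}]: both endpoints "
            f"{'oscillate' if lo_osc else 'are quiescent'}"
        )
    lo, hi = c_lo, c_hi
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if osc(mid) == lo_osc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
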