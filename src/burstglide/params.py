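"""Parameter containers for the burst-and-glide model.

All single-fish constants live in :class:`ModelParams`; everything specific to
the visual coupling of a pair lives in :class:`CouplingParams`.  Both are
frozen dataclasses and round-trip losslessly through flat dictionaries
(:meth:`to_dict` / :meth:`from_dict`), which is what the YAML/JSON config
layer serializes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping

__all__ = ["ModelParams", "CouplingParams", "LINEAR", "QUADRATIC"]

LINEAR = "linear"
QUADRATIC = "quadratic"


@dataclass(frozen=True)
class ModelParams:
    """Constants of the single-fish burst-and-glide oscillator.

    Parameters
    ----------
    a : float
        Propulsion amplitude (cm s^-2); the bursting force saturates at ``a``.
    k : float
        Drag coefficient (s^-1 for linear drag; for quadratic drag the decay
        term is ``(k*v)**2``).
    c : float
        Tonic input to the internal burst potential.  This is the single-fish
        bifurcation parameter: below the oscillation onset the fish cruises at
        constant speed, above it the fish bursts and glides.
    z1 : float
        Steepness of the propulsion sigmoid.
    b0 : float
        Burst-potential threshold of the propulsion sigmoid.
    drag : str
        Either ``"linear"`` (dv/dt = g(b) - k v) or ``"quadratic"``
        (dv/dt = g(b)^2 - (k v)^2).
    """

    a: float = 15.0
    k: float = 0.4
    c: float = 0.9255
    z1: float = 50.0
    b0: float = 0.0
    drag: str = LINEAR

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"propulsion amplitude a must be > 0, got {self.a}")
        if self.k <= 0:
            raise ValueError(f"drag coefficient k must be > 0, got {self.k}")
        if self.z1 <= 0:
            raise ValueError(f"sigmoid steepness z1 must be > 0, got {self.z1}")
        if self.drag not in (LINEAR, QUADRATIC):
            raise ValueError(f"drag must be 'linear' or 'quadratic', got {self.drag!r}")

    @classmethod
    def linear_defaults(cls, c: float = 0.9255, **kw: Any) -> "ModelParams":
        """Linear-drag defaults: k=0.4, a=15, z1=50, b0=0."""
        kw.setdefault("k", 0.4)
        return cls(c=c, drag=LINEAR, **kw)

    @classmethod
    def quadratic_defaults(cls, c: float = 0.7885, **kw: Any) -> "ModelParams":
        """Quadratic-drag defaults: k=0.8 (doubled to keep a similar speed range)."""
        kw.setdefault("k", 0.8)
        return cls(c=c, drag=QUADRATIC, **kw)

    def with_c(self, c: float) -> "ModelParams":
        return replace(self, c=c)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        return cls(**{f: d[f] for f in ("a", "k", "c", "z1", "b0", "drag") if f in d})


@dataclass(frozen=True)
class CouplingParams:
    """Visual-response coupling of the two-fish model.

    The follower sees the neighbour's relative position x_rel (other minus
    self, cm) and receives a boost ``f(x_rel) = d / (1 + exp(-z2 (x_rel - x0)))``
    to its tonic input.  ``f`` is logistic: it equals d/2 at the threshold
    distance ``x0``, saturates to ``d`` far ahead and vanishes far behind.

    ``gamma`` is the kinematic position gain: positions obey
    ``dx_i/dt = gamma * v_i``, i.e. one unit of the model speed variable moves
    the fish ``gamma`` cm per second.  The default gamma=10 sets the scale on
    which burst-and-glide excursions actually probe the response threshold
    x0 = 15 cm and is the value under which the documented regime sequence
    (constant / aperiodic / periodic / leader-follower / turn-taking) appears
    at d of order 0.01-0.07.
    """

    d: float = 0.02
    z2: float = 0.15
    x0: float = 15.0
    gamma: float = 10.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"coupling strength d must be >= 0, got {self.d}")
        if self.z2 <= 0:
            raise ValueError(f"response steepness z2 must be > 0, got {self.z2}")
        if self.gamma <= 0:
            raise ValueError(f"position gain gamma must be > 0, got {self.gamma}")

    def with_d(self, d: float) -> "CouplingParams":
        return replace(self, d=d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CouplingParams":
        return cls(**{f: d[f] for f in ("d", "z2", "x0", "gamma") if f in d})
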