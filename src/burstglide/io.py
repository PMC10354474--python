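"""Config files and trajectory CSV round-tripping.

A run config is a flat YAML/JSON mapping with the model keys (a, k, c, z1,
b0, drag), coupling keys (d, z2, x0, gamma) and simulation keys (t_end,
dt_out, rtol, atol, transient, seed).  Trajectories are written as CSV with a
JSON sidecar carrying the parameter snapshot.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .params import ModelParams, CouplingParams
from .integrate import SimSettings, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
]

_MODEL_KEYS = {"a", "k", "c", "z1", "b0", "drag"}
_COUPLING_KEYS = {"d", "z2", "x0", "gamma"}
_SIM_KEYS = {"t_end", "dt_out", "rtol", "atol", "transient", "method", "seed"}
_OTHER_KEYS = {"initial", "pair", "out"}


class RunConfig:
    """Parameter bundle for one reproducible run."""

    def __init__(
        self,
        params: ModelParams,
        coupling: CouplingParams | None = None,
        settings: SimSettings | None = None,
        initial: list[float] | None = None,
        pair: bool = False,
    ):
        self.params = params
        self.coupling = coupling
        self.settings = settings or SimSettings()
        self.pair = pair or coupling is not None
        if initial is None:
            initial = [0.0, 0.0, 0.0, 0.0, 0.0, 0.0] if self.pair else [0.0, 0.0]
        self.initial = list(map(float, initial))

    def to_dict(self) -> dict:
        out: dict[str, Any] = {}
        out.update(self.params.to_dict())
        if self.coupling is not None:
            out.update(self.coupling.to_dict())
        out.update({k: v for k, v in self.settings.to_dict().items() if v is not None})
        out["initial"] = self.initial
        out["pair"] = self.pair
        return out

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = _MODEL_KEYS | _COUPLING_KEYS | _SIM_KEYS | _OTHER_KEYS
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        params = ModelParams.from_dict(raw)
        coupling = CouplingParams.from_dict(raw) if (_COUPLING_KEYS & set(raw)) else None
        settings = SimSettings(**{k: raw[k] for k in _SIM_KEYS if k in raw})
        return cls(params, coupling, settings, raw.get("initial"), bool(raw.get("pair", False)))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML (or JSON: YAML is a superset) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path} does not contain a mapping")
    return RunConfig.from_dict(raw)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV (t, b1, v1[, x1, b2, v2, x2]) + JSON sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "params": traj.params.to_dict(),
        "coupling": traj.coupling.to_dict() if traj.coupling else None,
        "transient": traj.transient,
        "kind": traj.kind,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    The JSON sidecar restores the parameter snapshot; without a sidecar the
    caller gets default parameters (analyses that need the model RHS will
    then reflect those defaults).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c for c in ("b1", "v1", "x1", "b2", "v2", "x2") if c in df.columns]
    params, coupling, transient = ModelParams(), None, 0.0
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
        params = ModelParams.from_dict(meta["params"])
        if meta.get("coupling"):
            coupling = CouplingParams.from_dict(meta["coupling"])
        transient = float(meta.get("transient", 0.0))
    return Trajectory(df["t"].to_numpy(), df[cols].to_numpy(), params, coupling, transient)
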