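"""Run configuration: one documented YAML/JSON schema for all experiments.

A config document has the shape

.. code-block:: yaml

    experiment: simulate          # simulate | stability | phase-diagram | stochastic
    ecosystem:                    # or  scenario: winnowing | finite_pair | phase_scan
      q: 0.01
      strains:
        - {label: a, alpha: 1.0, omega: 1.0, r: 0.01}
        - {label: n, alpha: 2.0, omega: 0.0, r: 0.01}
    lam0: [1.0, 1.0]
    t_end: 1000.0                 # simulate
    options: {rtol: 1.0e-9, atol: 1.0e-12, extinction_threshold: 1.0e-6,
              divergence_cutoff: 1.0e6, time_variable: t}
    grid:                         # phase-diagram
      alpha_a_range: [0.5, 2.0]
      r_n_range: [1.0e-3, 1.0e-1]
      n_alpha: 21
      n_r: 21
    t_eval: 10000.0
    scheme: sde                   # stochastic: sde | host
    N: 4096
    seed: 0
    dt: 0.05
    generations: 2000

Unknown keys are rejected; defaults are materialized explicitly when the
config is echoed back.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .deterministic import IntegrationOptions
from .equilibrium import PhaseGridSpec
from .model_core import Ecosystem
from . import scenarios

__all__ = ["RunConfig", "load_config", "write_config"]

_EXPERIMENTS = ("simulate", "stability", "phase-diagram", "stochastic")
_TOP_KEYS = {
    "experiment", "ecosystem", "scenario", "lam0", "t_end", "options", "grid",
    "t_eval", "scheme", "N", "seed", "dt", "generations",
}


@dataclass(frozen=True)
class RunConfig:
    experiment: str
    eco: Ecosystem | None
    lam0: tuple[float, ...] | None
    t_end: float = 1000.0
    options: IntegrationOptions = field(default_factory=IntegrationOptions)
    grid: PhaseGridSpec | None = None
    t_eval: float = 1e4
    scheme: str = "sde"
    N: int = 4096
    seed: int = 0
    dt: float = 0.05
    generations: int = 2000

    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment,
            "ecosystem": None if self.eco is None else self.eco.to_dict(),
            "lam0": None if self.lam0 is None else [float(x) for x in self.lam0],
            "t_end": self.t_end,
            "options": dataclasses.asdict(self.options),
            "grid": None if self.grid is None else dataclasses.asdict(self.grid),
            "t_eval": self.t_eval,
            "scheme": self.scheme,
            "N": self.N,
            "seed": self.seed,
            "dt": self.dt,
            "generations": self.generations,
        }
        return d


def _build(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    doc = {k: v for k, v in doc.items() if v is not None}
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    experiment = doc.get("experiment", "simulate")
    if experiment not in _EXPERIMENTS:
        raise ValueError(f"experiment must be one of {_EXPERIMENTS}, got {experiment!r}")

    eco = None
    lam0 = None
    grid = None
    kwargs = {}
    if "scenario" in doc:
        if "ecosystem" in doc:
            raise ValueError("give either 'scenario' or 'ecosystem', not both")
        sc = scenarios.get(doc["scenario"])
        eco, lam0, grid = sc.eco, sc.lam0, sc.grid
        if sc.N is not None:
            kwargs["N"] = sc.N
        if sc.t_eval is not None:
            kwargs["t_eval"] = sc.t_eval
    elif "ecosystem" in doc:
        eco = Ecosystem.from_dict(doc["ecosystem"])
    elif experiment != "phase-diagram":
        raise ValueError("config needs an 'ecosystem' or a 'scenario'")

    if "lam0" in doc:
        lam0 = tuple(float(x) for x in doc["lam0"])
    elif lam0 is not None:
        lam0 = tuple(float(x) for x in lam0)
    if lam0 is None and eco is not None:
        lam0 = (1.0,) * eco.n_strains
    if eco is not None and lam0 is not None and len(lam0) != eco.n_strains:
        raise ValueError(f"lam0 has {len(lam0)} entries for {eco.n_strains} strains")
    if lam0 is not None and any(x < 0 for x in lam0):
        raise ValueError("initial copy numbers must be >= 0")

    if "options" in doc:
        opt_doc = dict(doc["options"])
        valid = {f.name for f in dataclasses.fields(IntegrationOptions)}
        unknown = set(opt_doc) - valid
        if unknown:
            raise ValueError(f"unknown integration option keys: {sorted(unknown)}")
        kwargs["options"] = IntegrationOptions(**opt_doc)
    if "grid" in doc:
        grid_doc = dict(doc["grid"])
        valid = {f.name for f in dataclasses.fields(PhaseGridSpec)}
        unknown = set(grid_doc) - valid
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        for key in ("alpha_a_range", "r_n_range", "lam0"):
            if key in grid_doc:
                grid_doc[key] = tuple(grid_doc[key])
        grid = PhaseGridSpec(**grid_doc)
    if experiment == "phase-diagram" and grid is None:
        grid = PhaseGridSpec()

    for key in ("t_end", "t_eval", "dt"):
        if key in doc:
            kwargs[key] = float(doc[key])
    for key in ("N", "seed", "generations"):
        if key in doc:
            kwargs[key] = int(doc[key])
    if "scheme" in doc:
        if doc["scheme"] not in ("sde", "host"):
            raise ValueError(f"scheme must be 'sde' or 'host', got {doc['scheme']!r}")
        kwargs["scheme"] = doc["scheme"]

    return RunConfig(experiment=experiment, eco=eco, lam0=lam0, grid=grid, **kwargs)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _build(doc)


def write_config(cfg: RunConfig, path) -> None:
    """Write the fully materialized config (all defaults explicit)."""
    path = Path(path)
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=False)
    path.write_text(text)


def roundtrip(cfg: RunConfig, path) -> RunConfig:
    write_config(cfg, path)
    return load_config(path)
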