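"""Bundled benchmark scenarios.

Three parameter sets exercise the three headline behaviors of the model:

* ``winnowing`` — six strains (three autonomous, three non-autonomous)
  started at one copy per host; competitive exclusion whittles the
  ecosystem down to a single autonomous/non-autonomous pair.
* ``phase_scan`` — the two-strain coexistence/collapse scan over
  (alpha_a, r_n) with alpha_a * alpha_n = 1, r_a * r_n = 1e-4, q = 1e-2,
  evaluated at t = 10000.
* ``finite_pair`` — the two-strain pair alpha_a = 1, alpha_n = 2,
  q = r_a = r_n = 1e-2 in a finite population of N = 4096 hosts, started
  from one copy of each per host.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import PhaseGridSpec, TwoStrainParams
from .model_core import Ecosystem, Strain

__all__ = ["winnowing", "finite_pair", "phase_scan", "SCENARIO_NAMES", "Scenario"]

SCENARIO_NAMES = ("winnowing", "phase_scan", "finite_pair")


@dataclass(frozen=True)
class Scenario:
    name: str
    eco: Ecosystem | None
    lam0: np.ndarray | None
    N: int | None = None
    t_eval: float | None = None
    grid: PhaseGridSpec | None = None


def winnowing() -> Scenario:
    """Six-strain winnowing scenario: alpha = (.75, .36, .50, .51, .58, .56),
    omega = (0, 0, 0, .61, .77, .42), q = 7.6e-4, r = 9.9e-3, lam0 = 1."""
    alphas = (0.75, 0.36, 0.50, 0.51, 0.58, 0.56)
    omegas = (0.0, 0.0, 0.0, 0.61, 0.77, 0.42)
    strains = tuple(
        Strain(label=f"strain_{i + 1}", alpha=a, omega=w, r=0.0099)
        for i, (a, w) in enumerate(zip(alphas, omegas))
    )
    eco = Ecosystem(strains=strains, q=0.00076)
    return Scenario(name="winnowing", eco=eco, lam0=np.ones(6))


def finite_pair() -> Scenario:
    """Two-strain finite-population scenario: alpha_a = 1, alpha_n = 2,
    q = r_a = r_n = 1e-2, N = 4096 hosts, lam0 = (1, 1)."""
    p = TwoStrainParams(alpha_a=1.0, alpha_n=2.0, r_a=1e-2, r_n=1e-2, q=1e-2)
    return Scenario(name="finite_pair", eco=p.to_ecosystem(), lam0=np.array([1.0, 1.0]), N=4096)


def phase_scan(n_alpha: int = 21, n_r: int = 21) -> Scenario:
    """Coexistence/collapse scan with the standard constraints."""
    grid = PhaseGridSpec(n_alpha=n_alpha, n_r=n_r)
    return Scenario(name="phase_scan", eco=None, lam0=None, t_eval=1e4, grid=grid)


def get(name: str, **kwargs) -> Scenario:
    try:
        return {"winnowing": winnowing, "finite_pair": finite_pair, "phase_scan": phase_scan}[
            name
        ](**kwargs)
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}") from None
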