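"""Mean-field time integration, extinction/divergence handling and
long-time diagnostics.

The central experiment this module supports is competitive winnowing: a
many-strain ecosystem integrated from small initial copy numbers loses
strains one by one until (generically) exactly one autonomous and one
non-autonomous strain persist. Integration can be carried out in natural
time ``t`` or in the rescaled time ``tau`` (``dt = (1 + A) dtau``), in
which the model is a generalized Lotka-Volterra system; the two
parameterizations trace the same orbits.

Strains whose mean copy number falls below ``extinction_threshold`` are
clamped to zero (zero is absorbing in the mean-field model, so clamping
only removes an asymptotically-dying exponential tail); a trajectory whose
total copy number exceeds ``divergence_cutoff`` is reported as diverged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import Ecosystem, MeanState, _as_lam, tau_drift, total_drift_vector

__all__ = [
    "IntegrationOptions",
    "Trajectory",
    "SurvivorReport",
    "integrate",
    "run_to_steady_state",
    "survivors",
    "long_time_averages",
    "stationarity_residuals",
    "cis_preference_drift",
]


@dataclass(frozen=True)
class IntegrationOptions:
    """Tolerances and thresholds for :func:`integrate`.

    The defaults are tuned for ecosystems whose equilibria span copy
    numbers of order 1e-1 to 1e1 while transients and dying strains pass
    through many decades on the way: tight tolerances (rtol 1e-9,
    atol 1e-12), an extinction threshold of 1e-6 mean copies per host and
    a divergence cutoff of 1e10 total mean copies. Stable multi-strain
    ecosystems can overshoot 1e7 total copies transiently before
    competitive exclusion brings them down, so the cutoff is set well
    above that; genuinely divergent orbits grow without bound and reach
    any cutoff quickly.
    """

    rtol: float = 1e-9
    atol: float = 1e-12
    extinction_threshold: float = 1e-6
    divergence_cutoff: float = 1e10
    time_variable: str = "t"  # "t" or "tau"
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.time_variable not in ("t", "tau"):
            raise ValueError(f"time_variable must be 't' or 'tau', got {self.time_variable!r}")


@dataclass(frozen=True)
class Trajectory:
    """Integrated orbit: times (strictly increasing), states (time x strain),
    the ecosystem, the time variable used, and a termination flag
    ('completed', 'diverged' or 'all_extinct')."""

    times: np.ndarray
    states: np.ndarray
    eco: Ecosystem
    time_variable: str
    termination: str
    options: IntegrationOptions

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (time, strain)."""
        n_t, n_s = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_s),
                "strain_label": np.tile(np.array(self.eco.labels, dtype=object), n_t),
                "lam": self.states.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        rep = None
        if self.termination != "diverged":
            rep = survivors(self, self.options.extinction_threshold)
        return {
            "termination": self.termination,
            "time_variable": self.time_variable,
            "t_final": float(self.times[-1]),
            "final_state": [float(x) for x in self.final_state],
            "survivors": None if rep is None else sorted(rep.surviving_indices),
            "n_autonomous_survivors": None if rep is None else rep.n_autonomous,
            "n_nonautonomous_survivors": None if rep is None else rep.n_nonautonomous,
            "ecosystem": self.eco.to_dict(),
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass(frozen=True)
class SurvivorReport:
    surviving_indices: frozenset[int]
    n_autonomous: int
    n_nonautonomous: int
    final_lams: np.ndarray


def _rhs(eco: Ecosystem, time_variable: str):
    if time_variable == "t":
        return lambda t, lam: total_drift_vector(np.maximum(lam, 0.0), eco)
    return lambda t, lam: tau_drift(np.maximum(lam, 0.0), eco)


def integrate(
    eco: Ecosystem,
    lam0,
    t_end: float,
    options: IntegrationOptions | None = None,
) -> Trajectory:
    """Integrate the mean-field drift from ``lam0`` to ``t_end``.

    Extinction threshold crossings are located by event detection; the
    crossing strain is clamped to zero and integration restarts. If the
    total copy number reaches ``divergence_cutoff`` the trajectory stops
    early with ``termination='diverged'``; if every strain is clamped the
    trajectory stops with ``termination='all_extinct'``.
    """
    options = options or IntegrationOptions()
    lam0 = np.asarray(lam0, dtype=float)
    if lam0.shape != (eco.n_strains,):
        raise ValueError(f"lam0 has {lam0.size} entries for {eco.n_strains} strains")
    if np.any(lam0 < 0):
        raise ValueError(f"initial copy numbers must be >= 0, got {lam0}")
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")

    rhs = _rhs(eco, options.time_variable)
    thr = options.extinction_threshold

    def make_extinction_event(i):
        def ev(t, lam):
            # only trigger for live strains well above the clamp
            return lam[i] - thr

        ev.terminal = True
        ev.direction = -1
        return ev

    def divergence_event(t, lam):
        return float(np.sum(lam)) - options.divergence_cutoff

    divergence_event.terminal = True
    divergence_event.direction = 1

    events = [make_extinction_event(i) for i in range(eco.n_strains)] + [divergence_event]

    t = 0.0
    lam = lam0.copy()
    times = [0.0]
    states = [lam.copy()]
    termination = "completed"
    if float(np.sum(lam)) >= options.divergence_cutoff:
        return Trajectory(
            times=np.array([0.0]), states=np.array([lam]), eco=eco,
            time_variable=options.time_variable, termination="diverged", options=options,
        )

    while t < t_end:
        sol = solve_ivp(
            rhs,
            (t, t_end),
            lam,
            method=options.method,
            rtol=options.rtol,
            atol=options.atol,
            events=events,
            dense_output=False,
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(
                f"integration failed at t = {sol.t[-1]:g}: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y[:, -1])):
            raise RuntimeError(f"non-finite state encountered; last valid time t = {sol.t[-2]:g}")
        # append, skipping the duplicated restart point
        times.extend(sol.t[1:].tolist())
        states.extend(np.maximum(sol.y[:, 1:].T, 0.0))
        t = sol.t[-1]
        lam = np.maximum(sol.y[:, -1], 0.0)
        if sol.status == 1:  # an event fired
            if sol.t_events[-1].size:  # divergence
                termination = "diverged"
                break
            for i in range(eco.n_strains):
                if sol.t_events[i].size:
                    lam[i] = 0.0
            states[-1] = lam.copy()
            if np.all(lam == 0.0):
                termination = "all_extinct"
                break
        else:
            break

    times = np.asarray(times)
    states = np.asarray(states)
    # drop occasional repeated time points produced by event restarts
    keep = np.concatenate([[True], np.diff(times) > 0])
    traj = Trajectory(
        times=times[keep],
        states=states[keep],
        eco=eco,
        time_variable=options.time_variable,
        termination=termination,
        options=options,
    )
    if termination == "completed" and np.all(traj.final_state < thr):
        traj = replace(traj, termination="all_extinct")
    return traj


def run_to_steady_state(
    eco: Ecosystem,
    lam0,
    options: IntegrationOptions | None = None,
    rate_tol: float = 1e-10,
    t_max: float = 1e6,
    t_first: float = 100.0,
) -> Trajectory:
    """Integrate until the surviving strains are stationary.

    "Stationary" means the largest per-capita rate ``|dlog lam_i/dt|``
    among strains above the extinction threshold is below ``rate_tol``;
    integration proceeds in doubling chunks and stops at ``t_max`` if the
    criterion is never met. This makes the qualitative notion "integrate
    to t = infinity" decidable.
    """
    options = options or IntegrationOptions()
    chunks: list[Trajectory] = []
    lam = np.asarray(lam0, dtype=float)
    t_done, t_chunk = 0.0, t_first
    while t_done < t_max:
        t_chunk = min(t_chunk, t_max - t_done)
        traj = integrate(eco, lam, t_chunk, options)
        traj = replace(traj, times=traj.times + t_done)
        chunks.append(traj)
        t_done += t_chunk
        lam = traj.final_state.copy()
        if traj.termination != "completed":
            break
        alive = lam >= options.extinction_threshold
        if not np.any(alive):
            break
        rhs = _rhs(eco, options.time_variable)
        rates = np.abs(rhs(0.0, lam)[alive] / lam[alive])
        if np.max(rates) < rate_tol:
            break
        t_chunk *= 2
    times = np.concatenate([c.times if i == 0 else c.times[1:] for i, c in enumerate(chunks)])
    states = np.vstack([c.states if i == 0 else c.states[1:] for i, c in enumerate(chunks)])
    return Trajectory(
        times=times,
        states=states,
        eco=eco,
        time_variable=options.time_variable,
        termination=chunks[-1].termination,
        options=options,
    )


def survivors(traj: Trajectory, extinction_threshold: float | None = None) -> SurvivorReport:
    """Strains whose final copy number is at or above the threshold."""
    if traj.termination == "diverged":
        raise ValueError("survivor analysis is undefined for a diverged trajectory")
    thr = traj.options.extinction_threshold if extinction_threshold is None else extinction_threshold
    final = traj.final_state
    idx = frozenset(int(i) for i in np.flatnonzero(final >= thr))
    mask = traj.eco.autonomous_mask
    return SurvivorReport(
        surviving_indices=idx,
        n_autonomous=int(sum(mask[i] for i in idx)),
        n_nonautonomous=int(sum(not mask[i] for i in idx)),
        final_lams=final.copy(),
    )


def long_time_averages(traj: Trajectory, burn_in_fraction: float = 0.5) -> tuple[float, float]:
    """Trapezoidal time-averages of the activities A and Omega over the
    post-burn-in window, in the trajectory's own time variable."""
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError(f"burn_in_fraction must lie in [0, 1), got {burn_in_fraction}")
    t0 = traj.times[0] + burn_in_fraction * (traj.times[-1] - traj.times[0])
    sel = traj.times >= t0
    if np.count_nonzero(sel) < 2:
        raise ValueError("fewer than 2 samples after burn-in")
    t = traj.times[sel]
    A = traj.states[sel] @ traj.eco.alpha
    Om = traj.states[sel] @ traj.eco.omega
    span = t[-1] - t[0]
    return float(np.trapezoid(A, t) / span), float(np.trapezoid(Om, t) / span)


def stationarity_residuals(eco: Ecosystem, A_bar: float, Omega_bar: float) -> np.ndarray:
    """Per-strain residual of the long-time balance condition
    ``alpha_i omega_i - r_i + alpha_i Omega_bar - (q omega_i + r_i) A_bar``.

    Any strain that persists with bounded orbits must have zero long-time
    average per-capita growth in tau, which is exactly this expression; a
    shared (A_bar, Omega_bar) solving it for n > 2 strains requires
    fine-tuned (coplanar) parameters, which is why generic stable
    ecosystems keep only one autonomous and one non-autonomous strain.
    """
    return (
        eco.alpha * eco.omega
        - eco.r
        + eco.alpha * Omega_bar
        - (eco.q * eco.omega + eco.r) * A_bar
    )


def cis_preference_drift(state, eco: Ecosystem) -> np.ndarray:
    """Sketch drift for a cis-preferring element pair (LINE/SINE-like).

    For a two-strain ecosystem (autonomous first) this evaluates, exactly
    as written in the reduced LINE/SINE literature model,

        dlam_a/dt = alpha_a * Omega - r_a
        dlam_n/dt = alpha_n * Omega * lam_a - r_n,   Omega = omega_a * lam_a.

    Because the transposase binds the transcript that produced it, the
    autonomous replication gain is *not* proportional to lam_a; the
    effective replication propensities (alpha_a / lam_a vs alpha_n) do not
    keep a constant ratio, which is the structural reason this ecosystem
    class self-stabilizes rather than sitting on a knife-edge.
    """
    lam = _as_lam(state, eco)
    if eco.n_strains != 2:
        raise ValueError(f"cis-preference comparison needs exactly 2 strains, got {eco.n_strains}")
    if not (eco.strains[0].is_autonomous and not eco.strains[1].is_autonomous):
        raise ValueError("expected the autonomous strain first and the non-autonomous second")
    a, n = eco.strains
    Omega = a.omega * lam[0]
    return np.array([a.alpha * Omega - a.r, n.alpha * Omega * lam[0] - n.r])
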