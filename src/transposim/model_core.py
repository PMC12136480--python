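"""Parameterization and mean-field drift of a transposon strain ecosystem.

A *strain* is a population of transposable elements sharing a replication
propensity ``alpha``, a transposase-production propensity ``omega`` and a
per-generation loss rate ``r``. Strains with ``omega > 0`` are autonomous
(they make their own replication machinery); strains with ``omega == 0``
are non-autonomous parasites that replicate only on transposase produced
by others. An :class:`Ecosystem` is a set of strains sharing a host
species, plus the per-replication host-kill probability ``q``.

Under random, frequent mating the per-host copy number of each strain is
Poisson, so the whole population state reduces to the vector of mean copy
numbers ``lam`` (per host). The mean-field drift of ``lam`` decomposes into

* transposition: ``alpha_i lam_i (omega_i + Omega) / (1 + A)``
* transpositional toxicity: ``-q lam_i omega_i A / (1 + A)``
* loss: ``-r_i lam_i``

with the activity sums ``A = sum_k alpha_k lam_k`` and
``Omega = sum_k omega_k lam_k``. The ``1/(1 + A)`` factor is a type-II
functional response: replication saturates when elements compete for a
limited transposase pool (multiplicative constants of the response are
absorbed into ``alpha`` and ``omega``). The drift is exposed in lam-space
(``dlam/dt``), so ``lam_i = 0`` is a regular point and extinction
boundaries are representable; the per-capita (log-space) form is recovered
by dividing by ``lam_i`` where positive.

The model is a first-order approximation: it assumes
``alpha_i << sum_k alpha_k lam_k`` for every strain and small ``q`` and
``r_i``. :func:`transposition_expectation_mc` evaluates the exact Poisson
expectation of the per-host replication rate by Monte Carlo so the
approximation can be checked; :func:`toxicity_drift_unreduced` keeps the
replication-feedback part of the toxicity covariance that the drift model
drops (it is suppressed by an additional ``1/(1 + A)`` and is second order
near equilibrium).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Strain",
    "Ecosystem",
    "MeanState",
    "DriftDecomposition",
    "transposition_drift",
    "toxicity_drift",
    "toxicity_drift_unreduced",
    "loss_drift",
    "total_drift",
    "total_drift_vector",
    "tau_drift",
    "interaction_matrix",
    "transposition_expectation_mc",
]

#: parameters above this are flagged by the validity report (the drift
#: equation is derived for small q and r)
SMALLNESS_WARN_THRESHOLD = 0.1


@dataclass(frozen=True)
class Strain:
    """One transposon strain: (alpha, omega, r) plus a label.

    alpha : replication propensity (dimensionless, >= 0)
    omega : transposase production propensity (dimensionless, >= 0)
    r     : per-generation loss rate (dimensionless, >= 0)
    """

    label: str
    alpha: float
    omega: float
    r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "omega", "r"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"strain {self.label!r}: {name} must be finite and >= 0, got {v}")

    @property
    def is_autonomous(self) -> bool:
        """A strain is autonomous iff it produces transposase (omega > 0)."""
        return self.omega > 0


@dataclass(frozen=True)
class Ecosystem:
    """An ordered set of strains plus the host-kill probability q."""

    strains: tuple[Strain, ...]
    q: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if len(self.strains) < 1:
            raise ValueError("an ecosystem needs at least one strain")
        labels = [s.label for s in self.strains]
        if len(set(labels)) != len(labels):
            raise ValueError(f"strain labels must be unique, got {labels}")
        if not (0.0 <= self.q < 1.0):
            raise ValueError(f"q must lie in [0, 1), got {self.q}")

    # -- array views -------------------------------------------------------
    @cached_property
    def alpha(self) -> np.ndarray:
        return np.array([s.alpha for s in self.strains])

    @cached_property
    def omega(self) -> np.ndarray:
        return np.array([s.omega for s in self.strains])

    @cached_property
    def r(self) -> np.ndarray:
        return np.array([s.r for s in self.strains])

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strains]

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @cached_property
    def autonomous_mask(self) -> np.ndarray:
        return np.array([s.is_autonomous for s in self.strains])

    # -- validity ----------------------------------------------------------
    def validity_report(self, threshold: float = SMALLNESS_WARN_THRESHOLD) -> list[str]:
        """Flag parameters outside the small-q, small-r regime the drift
        equation is derived in. Returns a list of human-readable warnings
        (empty when all parameters are comfortably small)."""
        warnings = []
        if self.q > threshold:
            warnings.append(f"q = {self.q:g} is not << 1 (threshold {threshold:g})")
        for s in self.strains:
            if s.r > threshold:
                warnings.append(
                    f"loss rate r = {s.r:g} of strain {s.label!r} is not << 1 (threshold {threshold:g})"
                )
        return warnings

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "q": float(self.q),
            "strains": [
                {"label": s.label, "alpha": float(s.alpha), "omega": float(s.omega), "r": float(s.r)}
                for s in self.strains
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ecosystem":
        allowed = {"q", "strains"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown ecosystem keys: {sorted(unknown)}")
        strains = []
        for sd in d["strains"]:
            s_unknown = set(sd) - {"label", "alpha", "omega", "r"}
            if s_unknown:
                raise ValueError(f"unknown strain keys: {sorted(s_unknown)}")
            strains.append(
                Strain(label=str(sd["label"]), alpha=float(sd["alpha"]),
                       omega=float(sd["omega"]), r=float(sd.get("r", 0.0)))
            )
        return cls(strains=tuple(strains), q=float(d.get("q", 0.0)))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Ecosystem":
        """Load from a YAML/JSON string or a file path."""
        try:
            import os
            is_path = os.path.exists(str(source)) and "\n" not in str(source)
        except (TypeError, ValueError):
            is_path = False
        if is_path:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclass(frozen=True)
class MeanState:
    """Mean copy numbers per host plus the cached activity sums."""

    lam: np.ndarray
    A: float
    Omega: float

    @classmethod
    def from_lam(cls, eco: Ecosystem, lam: Sequence[float]) -> "MeanState":
        lam = np.asarray(lam, dtype=float)
        _check_dims(lam, eco)
        if np.any(lam < 0):
            raise ValueError(f"mean copy numbers must be >= 0, got {lam}")
        return cls(lam=lam, A=float(eco.alpha @ lam), Omega=float(eco.omega @ lam))

    def consistent_with(self, eco: Ecosystem, rtol: float = 1e-12) -> bool:
        """Check the cached A, Omega against a recomputation."""
        return bool(
            np.isclose(self.A, eco.alpha @ self.lam, rtol=rtol, atol=1e-300)
            and np.isclose(self.Omega, eco.omega @ self.lam, rtol=rtol, atol=1e-300)
        )


@dataclass(frozen=True)
class DriftDecomposition:
    """Per-strain drift split into its three processes; total is their sum."""

    transposition: np.ndarray
    toxicity: np.ndarray
    loss: np.ndarray
    total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total is None:
            object.__setattr__(self, "total", self.transposition + self.toxicity + self.loss)


def _as_lam(state, eco: Ecosystem) -> np.ndarray:
    lam = state.lam if isinstance(state, MeanState) else np.asarray(state, dtype=float)
    _check_dims(lam, eco)
    return lam


def _check_dims(lam: np.ndarray, eco: Ecosystem) -> None:
    lam = np.asarray(lam)
    if lam.shape != (eco.n_strains,):
        raise ValueError(
            f"state has {lam.shape[0] if lam.ndim == 1 else lam.shape} entries "
            f"but the ecosystem has {eco.n_strains} strains"
        )


def transposition_drift(state, eco: Ecosystem) -> np.ndarray:
    """Mean-field transposition gain: ``alpha_i lam_i (omega_i + Omega)/(1+A)``."""
    lam = _as_lam(state, eco)
    A = eco.alpha @ lam
    Omega = eco.omega @ lam
    return eco.alpha * lam * (eco.omega + Omega) / (1.0 + A)


def toxicity_drift(state, eco: Ecosystem) -> np.ndarray:
    """Model-consistent toxicity loss: ``-q lam_i omega_i A/(1+A)``.

    Only the transposase-production channel of the toxicity covariance
    survives in the drift model; see :func:`toxicity_drift_unreduced` for
    the expression before the large-A reduction.
    """
    lam = _as_lam(state, eco)
    A = eco.alpha @ lam
    return -eco.q * lam * eco.omega * A / (1.0 + A)


def toxicity_drift_unreduced(state, eco: Ecosystem) -> np.ndarray:
    """Toxicity covariance before the large-A reduction:
    ``-q lam_i (alpha_i Omega + omega_i A)/(1+A)``.

    The ``alpha_i Omega`` piece is suppressed by an additional ``1/(1+A)``
    in a careful evaluation of the host-death covariance and is dropped
    from the drift model; this function is provided for diagnostics.
    """
    lam = _as_lam(state, eco)
    A = eco.alpha @ lam
    Omega = eco.omega @ lam
    return -eco.q * lam * (eco.alpha * Omega + eco.omega * A) / (1.0 + A)


def loss_drift(state, eco: Ecosystem) -> np.ndarray:
    """Loss / genetic-drift decay: ``-r_i lam_i``."""
    lam = _as_lam(state, eco)
    return -eco.r * lam


def total_drift(state, eco: Ecosystem) -> DriftDecomposition:
    """Full drift decomposition; ``total`` is the exact elementwise sum."""
    lam = _as_lam(state, eco)
    return DriftDecomposition(
        transposition=transposition_drift(lam, eco),
        toxicity=toxicity_drift(lam, eco),
        loss=loss_drift(lam, eco),
    )


def total_drift_vector(lam: np.ndarray, eco: Ecosystem) -> np.ndarray:
    """Fast path for integrators: ``dlam/dt`` without the decomposition."""
    alpha, omega, r, q = eco.alpha, eco.omega, eco.r, eco.q
    A = alpha @ lam
    Omega = omega @ lam
    return lam * ((alpha * (omega + Omega) - q * omega * A) / (1.0 + A) - r)


def interaction_matrix(eco: Ecosystem) -> np.ndarray:
    """Coefficient matrix ``M_ij = alpha_i omega_j - (q omega_i + r_i) alpha_j``
    of the generalized Lotka-Volterra form of the tau-dynamics."""
    alpha, omega, r, q = eco.alpha, eco.omega, eco.r, eco.q
    return np.outer(alpha, omega) - np.outer(q * omega + r, alpha)


def tau_drift(state, eco: Ecosystem) -> np.ndarray:
    """Drift in the rescaled time ``dt = (1 + A) dtau``:
    ``dlam_i/dtau = lam_i [alpha_i omega_i - r_i + sum_j M_ij lam_j]``.

    Equals ``total_drift * (1 + A)`` elementwise; in tau the model is a
    generalized Lotka-Volterra system.
    """
    lam = _as_lam(state, eco)
    growth = eco.alpha * eco.omega - eco.r + interaction_matrix(eco) @ lam
    return lam * growth


def transposition_expectation_mc(
    eco: Ecosystem,
    lam: Sequence[float],
    n_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the exact per-host transposition expectation.

    Draws per-host copy numbers ``phi_j ~ Poisson(lam_j)`` independently
    (linkage equilibrium) and averages the exact replication rate
    ``alpha_i phi_i (sum_j omega_j phi_j) / (1 + sum_k alpha_k phi_k)``.

    Returns ``(estimate, standard_error)`` per strain. The mean-field
    :func:`transposition_drift` should agree with the estimate to relative
    accuracy ``O(max_l alpha_l / sum_m alpha_m lam_m)`` plus Monte-Carlo
    error; the bound is asymptotic, so callers should allow for both terms.
    """
    lam = np.asarray(lam, dtype=float)
    _check_dims(lam, eco)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    est = np.zeros(eco.n_strains)
    var = np.zeros(eco.n_strains)
    # draw in blocks so memory stays modest for large n_samples
    block = 200_000 // max(eco.n_strains, 1) + 1
    done = 0
    sums = np.zeros(eco.n_strains)
    sumsq = np.zeros(eco.n_strains)
    while done < n_samples:
        m = min(block, n_samples - done)
        phi = rng.poisson(lam, size=(m, eco.n_strains))
        Omega_phi = phi @ eco.omega
        A_phi = phi @ eco.alpha
        rate = eco.alpha * phi * (Omega_phi / (1.0 + A_phi))[:, None]
        sums += rate.sum(axis=0)
        sumsq += (rate**2).sum(axis=0)
        done += m
    est = sums / n_samples
    var = sumsq / n_samples - est**2
    return est, np.sqrt(np.maximum(var, 0.0) / n_samples)
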