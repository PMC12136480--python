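import numpy as np
import pytest

from transposim import Ecosystem, Strain, TwoStrainParams


@pytest.fixture
def pair_params() -> TwoStrainParams:
    """Benchmark two-strain parameter set: alpha_a=1, alpha_n=2,
    q = r_a = r_n = 1e-2 (stable coexistence, lam0 = (0.3367, 33.0))."""
    return TwoStrainParams(alpha_a=1.0, alpha_n=2.0, r_a=1e-2, r_n=1e-2, q=1e-2)


@pytest.fixture
def pair_eco(pair_params) -> Ecosystem:
    return pair_params.to_ecosystem()


@pytest.fixture
def mixed_eco() -> Ecosystem:
    """Small mixed ecosystem used for hand-checked drift values."""
    return Ecosystem(
        strains=(Strain("a", alpha=1.0, omega=1.0, r=0.01), Strain("n", alpha=2.0, omega=0.0, r=0.02)),
        q=0.01,
    )


def random_ecosystem(rng: np.random.Generator, n_strains: int | None = None) -> Ecosystem:
    """Random ecosystem with at least one autonomous strain."""
    n = n_strains or int(rng.integers(1, 6))
    alphas = rng.uniform(0.1, 3.0, n)
    omegas = rng.uniform(0.0, 1.5, n) * (rng.random(n) < 0.6)
    if not np.any(omegas > 0):
        omegas[int(rng.integers(0, n))] = rng.uniform(0.1, 1.5)
    rs = 10 ** rng.uniform(-4, -1, n)
    q = 10 ** rng.uniform(-4, -1)
    return Ecosystem(
        strains=tuple(
            Strain(f"s{i}", alpha=float(alphas[i]), omega=float(omegas[i]), r=float(rs[i]))
            for i in range(n)
        ),
        q=float(q),
    )
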