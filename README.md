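# transposim

Population dynamics of transposable-element ecosystems: when do
autonomous transposons and the non-autonomous elements that parasitize
them coexist stably inside a host species, and when does the ecosystem
diverge or collapse?

Transposons are self-replicating DNA sequences. Autonomous elements
(e.g. autonomous helitrons) encode their own transposase; non-autonomous
elements carry no transposase gene and replicate only by stealing the
protein produced by their autonomous partners. `transposim` implements a
mechanistic model of this two-level parasitism in a sexually reproducing
host population, for theorists and genome biologists who want to explore
which parameter regimes keep real element families stable.

## The model

Each strain *i* carries a replication propensity α<sub>i</sub>, a
transposase-production propensity ω<sub>i</sub> (autonomous ⇔
ω<sub>i</sub> > 0) and a loss rate r<sub>i</sub>; replication kills the
host with probability *q*. Under random mating per-host copy numbers are
Poisson, so the state is the vector of mean copy numbers λ<sub>i</sub>.
With A = Σ α<sub>k</sub>λ<sub>k</sub> and Ω = Σ ω<sub>k</sub>λ<sub>k</sub>,

```
d log λi/dt = [αi (ωi + Ω) − q ωi A] / (1 + A) − ri ,
```

where 1/(1+A) is a type-II functional response (elements compete for a
finite transposase pool). In the rescaled time dt = (1+A) dτ this is a
generalized Lotka–Volterra system. The package provides:

* **model core** — strain/ecosystem types, the drift decomposed into
  transposition, toxicity and loss, YAML/JSON serialization, and a
  Monte-Carlo Poisson oracle for the underlying approximation;
* **deterministic dynamics** — stiff-capable integration with extinction
  clamping and divergence detection, survivor reports, long-time
  averages, and a cis-preference (LINE/SINE-style) comparison model;
* **equilibrium analysis** — for the one-autonomous/one-non-autonomous
  pair (ω<sub>a</sub> normalized to 1): the closed-form fixed point
  λ<sub>a</sub>⁰ = r<sub>n</sub>(q+α<sub>a</sub>)/D with
  D = α<sub>n</sub>(r<sub>a</sub>+q) − α<sub>a</sub>r<sub>n</sub>, exact
  eigenvalues, and the coexistence criterion
  **(q+r<sub>a</sub>)/α<sub>a</sub> > r<sub>n</sub>/α<sub>n</sub> and
  α<sub>n</sub> > α<sub>a</sub>** — the parasite must out-compete its
  provider for transposase — plus phase-diagram scans over parameter
  grids;
* **stochastic finite populations** — an Euler–Maruyama SDE with mating
  noise σ<sub>i</sub>² = 2λ<sub>i</sub>/N per generation, the stationary
  covariance Σ from the Lyapunov equation JΣ + ΣJᵀ + Q = 0, and an
  individual-based simulator executing mating, transposition, host death
  and loss on an explicit N × strains copy-number matrix.

Two equilibrium predictions fall out and match what is seen in natural
element censuses: autonomous elements are rare
(λ<sub>a</sub>⁰/λ<sub>n</sub>⁰ ≈ r<sub>n</sub>) and per-element
transposition rates are low (≈ r<sub>n</sub>).

## Worked example

```python
import numpy as np
import transposim as tx

# six-strain competition: who survives?
sc = tx.scenarios.winnowing()
traj = tx.run_to_steady_state(sc.eco, sc.lam0)
rep = tx.survivors(traj)
print("survivors:", sorted(rep.surviving_indices),
      f"({rep.n_autonomous} autonomous, {rep.n_nonautonomous} non-autonomous)")
print("final copy numbers:", np.round(rep.final_lams, 3))

# two-strain equilibrium theory
p = tx.TwoStrainParams(alpha_a=1.0, alpha_n=2.0, r_a=0.01, r_n=0.01, q=0.01)
fp = tx.fixed_point(p)
print(f"fixed point: lam_a0 = {fp.lam_a0:.4f}, lam_n0 = {fp.lam_n0:.3f}")
print("phase:", tx.classify(p).phase)
lam1, lam2 = tx.eigenvalues_closed_form(p)
print(f"eigenvalues: {lam1:.4f}, {lam2:.4f}")
pred = tx.equilibrium_predictions(p)
print(f"abundance ratio lam_a0/lam_n0 = {pred.ratio:.4f}  (r_n = {pred.r_n})")
print(f"per-element transposition rate = {pred.per_element_rate:.4f}")

# finite population of N = 4096 hosts
fm = tx.lyapunov_covariance(p, N=4096)
print("fluctuation SDs:", np.round(np.sqrt(np.diag(fm.Sigma)), 4))
```

prints

```
survivors: [0, 4] (1 autonomous, 1 non-autonomous)
final copy numbers: [207.319   0.      0.      0.      2.71    0.   ]
fixed point: lam_a0 = 0.3367, lam_n0 = 32.998
phase: coexistence
eigenvalues: -0.1650+0.7996j, -0.1650-0.7996j
abundance ratio lam_a0/lam_n0 = 0.0102  (r_n = 0.01)
per-element transposition rate = 0.0101
fluctuation SDs: [ 0.1679 10.5069]
```

Of six competing strains only one autonomous/non-autonomous pair
persists; the two-strain pair (α<sub>a</sub>=1, α<sub>n</sub>=2,
q=r<sub>a</sub>=r<sub>n</sub>=0.01) sits in the coexistence phase, its
fixed point is a stable spiral (complex eigenvalue pair with negative
real part), the parasite outnumbers its provider 100:1, the per-element
transposition rate equals the parasite loss rate to 1%, and in a
population of 4096 hosts the stationary fluctuation SDs around
(0.337, 33.0) are (0.17, 10.5).

The same experiments are available from the shell:

```
transposim scenario winnowing
transposim simulate|stability|phase-diagram|stochastic --config cfg.yaml --out rundir
```

Each run directory contains a fully materialized config echo, tidy CSV
tables and a JSON summary; stochastic runs are bit-reproducible from the
recorded seed.

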