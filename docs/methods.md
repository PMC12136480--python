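# Methods

## Model

A *strain* is a population of transposable elements sharing three
dimensionless per-generation propensities: replication α ≥ 0,
transposase production ω ≥ 0, and loss r ≥ 0; a strain is autonomous iff
ω > 0. An *ecosystem* is an ordered set of strains plus a per-replication
host-kill probability q ∈ [0, 1). The host population reproduces
sexually with random, frequent, indiscriminate mating, which keeps
per-host copy numbers φ<sub>i</sub> Poisson (linkage equilibrium), so the
population state reduces to the means λ<sub>i</sub> = ⟨φ<sub>i</sub>⟩.

The per-host replication rate of strain *i* is
α<sub>i</sub>φ<sub>i</sub>·Ω<sub>φ</sub>·R(A<sub>φ</sub>), where
Ω<sub>φ</sub> = Σω<sub>j</sub>φ<sub>j</sub> is the transposase supply,
A<sub>φ</sub> = Σα<sub>k</sub>φ<sub>k</sub> the competing demand, and
R(x) = 1/(1+x) a Holling type-II functional response (the response's
multiplicative constants are absorbed into α and ω; the general form is
deliberately not a runtime parameter). Taking Poisson expectations with
the factorial-moment identity ⟨φ f(φ)⟩ = λ⟨f(φ+1)⟩ and assuming
α<sub>j</sub> ≪ A for every j gives the mean-field drift used throughout:

    dλi/dt = λi [ αi(ωi + Ω) − q ωi A ] / (1 + A) − ri λi ,

with A = Σα<sub>k</sub>λ<sub>k</sub>, Ω = Σω<sub>k</sub>λ<sub>k</sub>.
The three addends are exposed as a `DriftDecomposition`
(transposition + toxicity + loss = total, exactly).

**Toxicity term.** The intermediate covariance expression for
replication-triggered host death is
−qλ<sub>i</sub>(α<sub>i</sub>Ω + ω<sub>i</sub>A)/(1+A); a careful
evaluation shows the α<sub>i</sub>Ω piece is suppressed by an additional
factor 1/(1+A) (and is O(q·r) near equilibrium, where Ω/A ~ λa/λn), so
the model drift keeps only the −qλ<sub>i</sub>ω<sub>i</sub>A/(1+A)
channel. The unreduced expression is available as
`toxicity_drift_unreduced` for diagnostics. Constant (non-replication)
fitness costs are not a separate term; they are modelled by inflating r.

**Validity.** The drift is first order in (q, r) and in max α/A. An
`Ecosystem.validity_report()` flags q or r above 0.1, and
`transposition_expectation_mc` evaluates the exact Poisson expectation
of the per-host rate by Monte Carlo; tests compare it to the mean-field
term with the combined tolerance (max α/A)·drift + 3 MC standard errors.

## Deterministic dynamics

In rescaled time dt = (1+A)dτ the model is generalized Lotka–Volterra:
dλ<sub>i</sub>/dτ = λ<sub>i</sub>[α<sub>i</sub>ω<sub>i</sub> − r<sub>i</sub> + Σ<sub>j</sub>M<sub>ij</sub>λ<sub>j</sub>],
M<sub>ij</sub> = α<sub>i</sub>ω<sub>j</sub> − (qω<sub>i</sub>+r<sub>i</sub>)α<sub>j</sub>.
Integration (LSODA, rtol 1e−9, atol 1e−12) runs in λ-space, where
λ<sub>i</sub> = 0 is a regular (absorbing) point, in either time
variable. Numerical choices:

* **Extinction threshold 1e−6** mean copies per host: a strain crossing
  it downward is clamped to zero by event detection. Zero is absorbing in
  the exact model, and equilibria of interest are O(10⁻¹)–O(10²), so
  clamping only truncates an asymptotically-dying exponential tail.
* **Divergence cutoff 1e10** total mean copies (terminal event). Stable
  multi-strain ecosystems can overshoot transiently — the bundled
  six-strain winnowing scenario peaks at ~3.4e7 total copies near t ≈ 400
  before relaxing to a two-strain equilibrium of ~2e2 — so the cutoff
  sits well above any observed stable transient; genuinely divergent
  orbits grow without bound and reach any cutoff quickly.
* **"Integrate to t = ∞"** is operationalized by `run_to_steady_state`:
  doubling time chunks until max |dlog λ<sub>i</sub>/dt| < 1e−10 among
  surviving strains, or t = 1e6.

`long_time_averages` returns trapezoidal time-averages of A and Ω over a
post-burn-in window in the trajectory's own time variable; any persistent
strain must satisfy the balance
α<sub>i</sub>ω<sub>i</sub> − r<sub>i</sub> + α<sub>i</sub>Ω̄ − (qω<sub>i</sub>+r<sub>i</sub>)Ā = 0,
which is why generic stable ecosystems retain exactly one autonomous and
one non-autonomous strain (three or more balance vectors are coplanar
only under fine-tuning).

`cis_preference_drift` implements the reduced LINE/SINE-style sketch
(dλ<sub>a</sub>/dt = α<sub>a</sub>Ω − r<sub>a</sub>,
dλ<sub>n</sub>/dt = α<sub>n</sub>Ωλ<sub>a</sub> − r<sub>n</sub>, Ω = ω<sub>a</sub>λ<sub>a</sub>)
exactly as written in that literature, including the non-λ-proportional
loss terms. As written the sketch has no functional response and its
orbits are not globally bounded; what the package asserts about it is
the structural stabilization mechanism only — the parasite's relative
replication gain grows ∝ λ<sub>a</sub>, so the effective propensity
ratio cannot sit on a knife-edge.

## Two-strain equilibrium theory

For one autonomous and one non-autonomous strain, ω<sub>a</sub> is
normalized to 1 by rescaling (r<sub>a</sub>, r<sub>n</sub>, τ). With
D = α<sub>n</sub>(r<sub>a</sub>+q) − α<sub>a</sub>r<sub>n</sub>, the
interior fixed point is

    lam_a0 = r_n (q + alpha_a) / D
    lam_n0 = [alpha_a alpha_n − r_a alpha_n + r_n alpha_a (1 − q − alpha_a)] / (alpha_n D)

(leading order: r<sub>n</sub>α<sub>a</sub>/D and α<sub>a</sub>/D). It
exists iff both coordinates are positive, equivalently (for small
parameters) (q+r<sub>a</sub>)/α<sub>a</sub> > r<sub>n</sub>/α<sub>n</sub>;
D = 0 sends it to infinity and raises an error.

**Eigenvalues.** At the fixed point the τ-Jacobian is
J<sub>τ</sub> = diag(λ⁰)M, and `eigenvalues_closed_form` returns its
exact spectrum from the symbolic trace and determinant
(tr = λ<sub>a</sub>⁰α<sub>a</sub>(1−q−r<sub>a</sub>) − λ<sub>n</sub>⁰r<sub>n</sub>α<sub>n</sub>,
det = λ<sub>a</sub>⁰λ<sub>n</sub>⁰α<sub>n</sub>D). At the benchmark
parameters (α<sub>a</sub>=1, α<sub>n</sub>=2, q=r<sub>a</sub>=r<sub>n</sub>=0.01)
the spectrum is a stable spiral, −0.165 ± 0.800i. The compact literature
expression
[α<sub>a</sub>−α<sub>n</sub> ± √((α<sub>a</sub>−α<sub>n</sub>)² − 4α<sub>a</sub>α<sub>n</sub>²r<sub>n</sub>((q+r<sub>a</sub>)/α<sub>a</sub> − r<sub>n</sub>/α<sub>n</sub>))]/2
is provided as `eigenvalues_trace_approximation`: its real-part signs
match the exact spectrum (stable iff the fixed point exists and
α<sub>n</sub> > α<sub>a</sub>), but its magnitudes do not — its trace is
α<sub>a</sub>−α<sub>n</sub> whereas the exact trace is
≈ λ<sub>a</sub>⁰(α<sub>a</sub>−α<sub>n</sub>) — so it must not be used
for quantitative decay rates. Tests cross-check the exact closed form
against central-difference Jacobians to 1e−8 relative over 10⁴ random
parameter draws.

**Phase classification.** `classify` applies the two inequalities
literally: coexistence, collapse (no fixed point), collapse (unstable),
or marginal when α<sub>a</sub> = α<sub>n</sub> exactly — the knife-edge
on which earlier equal-propensity models implicitly sat; marginal is
never reported stable. The inequality α<sub>n</sub> > α<sub>a</sub> is
itself the leading order of tr J < 0: the exact stability boundary is
displaced from the marginal line by first-order terms
q(1−α<sub>a</sub>) − r<sub>a</sub>α<sub>a</sub> + r<sub>a</sub>α<sub>n</sub>/α<sub>a</sub> − r<sub>n</sub>(1−α<sub>a</sub>−q),
so criterion/eigenvalue sign agreement is asserted only outside a band
of three times that width around α<sub>a</sub> = α<sub>n</sub>.

**Phase scan.** `phase_diagram` integrates a log-spaced
(α<sub>a</sub>, r<sub>n</sub>) grid under the constraints
α<sub>a</sub>·α<sub>n</sub> = 1, r<sub>a</sub>·r<sub>n</sub> = 1e−4,
q = 1e−2 (all configurable), from λ(0) = (1, 1) to t = 1e4, in log
copy-number space: near-marginal stable spirals dip to λ ~ e⁻¹⁵⁰ and
back, which underflows fatally in linear space. The scan's divergence
cutoff is 1e15 because those same spirals peak at ~2.4e12 before
damping (measured over the default grid), while genuinely divergent
orbits pass any cutoff within tens of time units. On the default grid
the largest coexistence-phase equilibrium total is ~4e2 and the smallest
escaping total at t = 1e4 is ~8e5, so "escaped" (diverged or total
> 1e4) cleanly separates the empirical phases; near-marginal stable
points may sit mid-transient (total anywhere from 1e−8 to 1e2) at
t = 1e4, which is inherent to a fixed-horizon scan, not to the
classification.

**Equilibrium predictions.** At a stable fixed point the abundance ratio
λ<sub>a</sub>⁰/λ<sub>n</sub>⁰ and the per-element transposition rate
λ<sub>a</sub>(α<sub>a</sub>+A)/((1+A)(λ<sub>a</sub>+λ<sub>n</sub>))
(total transposition gain over total copies) both approach
r<sub>n</sub> as q, r → 0; `equilibrium_predictions` returns both with
their relative deviations from r<sub>n</sub> (2.0% and 1.0% at the
benchmark set).

## Finite populations

Near a stable fixed point, fluctuations of λ are modelled as an
Ornstein–Uhlenbeck process: drift Jacobian
J = diag(λ⁰)M/(1+A⁰) (natural time) and diagonal mating-noise diffusion
Q<sub>ii</sub> = 2γλ<sub>i</sub>⁰/N, γ = 1 generation per unit time by
default. `lyapunov_covariance` solves JΣ + ΣJᵀ + Q = 0
(SciPy's Bartels–Stewart solver), requires all Re(eig J) < 0, symmetrizes
Σ, and reports the residual (< 1e−10 in all tested instances; tests
cross-check against an independent Kronecker-product solve and the
quadrature ∫e<sup>Jt</sup>Qe<sup>Jᵀt</sup>dt).

`sde_simulate` is Euler–Maruyama with the full nonlinear drift,
per-strain noise √(2γλ<sub>i</sub>/N)dW, states floored at 0, dt ≤ 0.1
generations, one explicitly seeded generator (bit-reproducible). The
diffusion includes mating noise only; transposition/toxicity/loss shot
noise is O(α, q, r) smaller near equilibrium and is omitted from the SDE
(it is present mechanistically in the host simulator).

**Accuracy of the linearized covariance.** The Lyapunov Σ describes the
SDE's stationary variance only where fluctuations are small against the
mean. At the benchmark pair with N = 4096, √Σ<sub>nn</sub>/λ<sub>n</sub>⁰ ≈ 32%,
and the measured stationary variance of the nonlinear SDE exceeds the
linear prediction by ×1.5 (λ<sub>a</sub>) to ×1.9 (λ<sub>n</sub>) — the
multiplicative √λ noise and drift curvature inflate second moments. The
inflation vanishes ~1/N (×1.08 at N = 16384, ×0.98 at N = 65536), and a
linear OU simulation with the same integrator reproduces Σ to 2–3%,
validating solver and integrator separately. The acceptance suite
asserts the 20%-level agreement at N = 4096 and therefore fails there by
design of the study conditions; the large-N agreement is asserted in a
separate test. Single-orbit band statements (staying within 4√Σ of the
equilibrium) are insensitive to this inflation and hold at N = 4096.

`host_simulate` executes, per generation and in a fixed documented order
on one seeded generator: (1) biparental mating — each of N offspring
draws two uniform parents and inherits each parental element
independently with probability 1/2 (preserves Poisson marginals and
linkage equilibrium by thinning/superposition); (2) transposition —
per-host Poisson events with mean α<sub>i</sub>φ<sub>i</sub>Ω<sub>φ</sub>/(1+A<sub>φ</sub>),
capped at 10 per strain per generation (the model's regime has rates
≪ 1); (3) toxicity — each replication event kills its host with
probability q (death after replication, the new copy dies with the
host); dead hosts are replaced by copies of uniformly chosen survivors,
keeping N fixed; (4) loss — independent binomial thinning at rate
r<sub>i</sub>. An all-dead generation raises a population-collapse error.

Two mechanistic limits are documented rather than hidden:

* **Mating-noise coefficient.** The analytic theory carries
  σ² = 2λ/N per generation; the implemented biparental scheme measurably
  delivers λ/N (each offspring count is an independent draw of variance
  (λ + Var φ)/2 = λ for Poisson φ). `mating_variance_report` measures the
  rate under pure mating and reports it against both coefficients; the
  test suite asserts the measured value (≈ λ/N, i.e. half the theory
  coefficient). The SDE and Lyapunov Q deliberately keep the 2λ/N of the
  analytic theory, so host-level fluctuations run ≈ half the SDE
  variance.
* **Validity regime for host runs.** The drift comparison holds to
  relative O((α<sub>a</sub>+α<sub>n</sub>)/A) plus O(q+r)
  within-generation process coupling (loss and toxicity act on
  same-generation transposition gains); one-generation drift tests
  therefore use the combined tolerance 3 SE + that budget, and a
  dedicated test pins the predicted deficit at a high-rate state.
  Mean-field orbits launched from λ = (1, 1) at the benchmark pair pass
  through per-host replication rates ~90/generation, where any
  discrete-generation implementation saturates (with the event cap the
  simulator locks onto an artificial equilibrium at λ ≈ cap/r), so
  host-based equilibrium runs are initialized near the fixed point; the
  SDE, whose drift is uncapped, follows the full orbit from (1, 1).

## Synthetic scenarios

The bundled scenarios define the package's benchmark conditions:
`winnowing` (six strains, α = {.75, .36, .50, .51, .58, .56},
ω = {0, 0, 0, .61, .77, .42}, q = 7.6e−4, r = 9.9e−3, λ(0) = 1),
`finite_pair` (α<sub>a</sub> = 1, α<sub>n</sub> = 2,
q = r<sub>a</sub> = r<sub>n</sub> = 1e−2, N = 4096, λ(0) = (1, 1)) and
`phase_scan` (the constrained grid above, t_eval = 1e4). They emulate
idealized element families: dimensionless propensities, no mutation
between strains, no host demography or structured mating, and toxicity
only through replication events. Passing tests therefore demonstrate
internal consistency of model, theory and simulators under these
idealized conditions — not calibration to any measured element family.

## Known limitations

* No strain-to-strain mutation, host population structure, selfing or
  assortative mating, or host fitness effects beyond q-toxicity.
* The drift model is first order in (q, r, max α/A); conclusions for
  parameter regimes with per-host rates approaching 1 are outside its
  domain.
* The phase scan reproduces boundary structure, not any particular
  rendering: axes, resolution and color scale of published heatmaps are
  not part of the contract.
* The Fokker–Planck equation is never solved directly; fluctuations come
  from SDE sampling and the stationary Lyapunov covariance.
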