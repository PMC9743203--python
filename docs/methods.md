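# Methods

## Model and procedure

The package treats barrier crossing as a first-passage problem for a single
particle obeying underdamped Langevin dynamics on an analytic potential
U(x):

    m dv = −∇U dt − m γ v dt + √(2 m γ k_B T) dW,

integrated with the BAOAB splitting. A trajectory starts from a
configured initial condition (fixed point or Gaussian) with velocities
drawn from the Maxwell–Boltzmann distribution, and its first-passage time
(FPT) τ is the global elapsed time at which a chosen coordinate first
crosses a threshold.

Stochastic resetting interrupts the trajectory at protocol-determined
times and replaces the state by a fresh i.i.d. draw of the initial
condition — position from the initializer *and* velocity from
Maxwell–Boltzmann (a full reset; a position-only reset would leave the
particle with a correlated velocity and is not what "i.i.d. initial
conditions" means). The global clock is never rewound. Two protocols are
implemented: Poisson (intervals ~ Exp(1/r)) and sharp (fixed period T).
Because reset intervals are pre-drawn rather than realized as per-step
Bernoulli trials, the protocol law is exact and independent of the
timestep; the *application* of a reset, like passage detection, happens on
step boundaries.

Why resetting helps: for a broad FPT distribution the mean is dominated by
rare slow excursions; restarting abandons those excursions. The classical
sufficient condition is COV = std/mean > 1, equivalently a negative slope
of the Poisson reset-mean curve at r = 0, since
d⟨τ⟩_r/dr |₀ = ⟨τ⟩²(1 − COV²)/2. Among all protocols at their own optimum,
sharp resetting is never worse than Poisson; both orderings are verified
numerically on inverse-Gaussian families.

## Inference of reset-free kinetics

Poisson resetting at rate r is statistically identical to resetting at a
lower rate r* superposed with an independent Poisson clock of rate
r − r*. Applying the standard renewal identity for restarted processes to
that decomposition gives, for any r > r*,

    ⟨τ⟩_r = (1 − f̃_{r*}(r − r*)) / ((r − r*) f̃_{r*}(r − r*)),

with f̃_{r*}(s) = E[e^{−sτ}] the Laplace transform of the FPT law *at* r*.
The transform is estimated as the arithmetic mean of e^{−sτ_j}; its
standard error is the sample standard deviation of e^{−sτ_j} over √N, and
the prediction's SE follows by the delta method (|d⟨τ⟩/df̃| = 1/(s f̃²)).
The identity is never trusted as algebra alone: an independent brute-force
oracle — renewal simulation of min(τ, R) chains resampled from the
empirical distribution — must agree with it within combined standard
errors on exponential, deterministic, inverse-Gaussian and simulated
double-well inputs, and this agreement is part of the test suite.

The reset-free mean is recovered by evaluating the prediction on a grid of
20 rates equally spaced in [r*, 2r*], fitting a least-squares polynomial
of degree 4 in the scaled offset t = (r − r*)/r* (curve scaled by the
sample mean for conditioning; Vandermonde condition number guarded), and
evaluating the fit at t = −1, i.e. r = 0. Uncertainty comes from a
percentile bootstrap over the FPT sample (200 resamples, 95% interval):
the delta-method error of a degree-4 extrapolation is unreliable, and the
bootstrap automatically carries the strong correlation between grid points
(all predictions share the same sample). Extrapolating backwards over a
distance r* is the method's intrinsic bias–acceleration trade-off: the
error of ⟨τ⟩₀ grows with r* while the speedup grows too, so r* should be
chosen as small as the available budget allows.

The optimal-rate search minimizes the predicted curve over a log-spaced
grid (default 60 points spanning [0.1/mean, 30/mean]) with golden-section
refinement between the bracketing grid points. Two guards matter in
practice: grid rates at which the empirical transform rests on an
effective sample size below 25 (weights e^{−sτ} concentrated on a handful
of fast passages) are dropped, because the predicted curve there is noise;
and a minimum that improves on the r* mean by less than 2 SE is reported
as "resetting not beneficial" rather than as an optimum — deterministic
(COV = 0) and exponential (COV = 1) inputs must land in that branch.
Inference demands uncensored input with Poisson (or reset-free)
provenance; sharp-resetting ensembles are rejected explicitly because the
superposition argument does not apply to them.

## Synthetic data

Two generator layers stand in for expensive molecular simulations.

**Analytic FPT models.** Exponential(k), deterministic(τ₀) and inverse
Gaussian IG(μ, λ) (the FPT law of drift–diffusion to an absorbing
boundary, COV = √(μ/λ)) with closed-form transforms, reset means
(quadrature where no closed form exists) and samplers. The benchmark
default is μ = 1000 ps with λ = 250 ps, i.e. COV = 2, so that resetting is
beneficial and the inference problem is non-trivial. The IG sampler is the
Michael–Schucany–Haas chi-square transformation with probabilistic root
selection, cross-checked against an independent library implementation by
a KS test.

**Model potentials.** Parameters are configuration data calibrated to the
benchmark constraints, re-derived by `scripts/calibrate_potentials.py`:

- *Double well*, U = ½kx² + A e^{−x²/2σ²}. Given σ = 0.75 Å, requiring
  minima at ±3 Å and a 1 kT barrier fixes (k, A) in closed form
  (k ≈ 0.149, A ≈ 250.2 internal units). The spring is soft: excursions
  to |x| ≈ 100 Å cost ≈ 3 kT, which is what makes the FPT distribution
  broad (simulated COV ≈ 1.8) — the particle wanders far before returning
  to cross.
- *Entropic two-basin*, U = a(x² − x_m²)² + ½κ(x)y², with κ interpolated
  *geometrically* (tanh switch of width 0.4 Å in log κ) between
  k_B T/(0.5 Å)² on the left and k_B T/(50 Å)² on the right. The log-space
  switch is what keeps both extreme widths accurate to ~1% at x = ∓1.3 Å;
  a linear κ switch cannot reproduce a 10⁴ stiffness ratio without
  contaminating the soft side. Trapping here is entropic: the right basin
  is isoenergetic with the left but 100× wider in y, so the particle
  rarely sits at the small |y| from which crossing is possible.
- *Three-well Wolfe–Quapp-style surface*. Rather than calibrating a
  rotated quartic polynomial against four independent barrier targets — an
  opaque optimization with no guarantee of a clean three-minimum topology —
  the surface is assembled from parts whose roles are separable: a quartic
  substate pair in x (minima ±15 Å, 1.5 kT sub-barrier), a quartic
  inter-basin profile in y (6.25 kT ridge), a tanh switch in y that
  collapses the substate pair into one harmonic upper well, and a
  one-sided ridge term (+3.75 kT, active at x > 0) that raises the *direct*
  escape barrier of the right substate to ~10 kT. Every printed constraint
  is then satisfied by construction and verified numerically. Note the
  minimax (path) barrier from the right substate to the upper basin is
  ≈ 6.3 kT — the cheapest route detours through the left substate — which
  is exactly why the right substate acts as a long-lived decoy;
  `verify_constraints` therefore checks the 10 kT figure as a straight-line
  ("slice") barrier and the others as minimax barriers.

What the generators do *not* emulate: many-body force fields, solvent
friction heterogeneity, multi-dimensional reaction coordinates with
hidden slow modes, or the censoring patterns of wall-clock-limited MD
campaigns. Passing tests therefore demonstrate the correctness of the
resetting/inference machinery and the integrator on systems whose truth is
known — not that any particular molecular system will show a given
speedup. The import path for external FPT samples (CSV with provenance
headers) is exercised on synthetic stand-ins only.

## Numerical choices

- **Integrator**: BAOAB, dt = 4 fs for the model potentials (2 fs for the
  entropic model, whose switching wall steepens the force), friction
  γ = 1 ps⁻¹, mass 40 amu, T = 300 K, k_B = 0.83144626 amu·Å²·ps⁻²·K⁻¹
  (unit system Å/ps/amu, energies in amu·Å²·ps⁻²). A dt-halving check on
  the double-well mean FPT guards discretization bias at the 3-combined-SE
  level.
- **Event order** within a step: integrate → check passage → check reset,
  so a passage and a reset in the same step count as passage. Passage is
  detected on discrete steps without interpolation (bias ≤ dt, negligible
  against picosecond-scale means).
- **RNG**: one root seed; per-trajectory streams spawned via
  `SeedSequence`, so ensembles are reproducible, order-independent, and
  prefix-stable (enlarging an ensemble extends it without changing
  existing trajectories).
- **Censoring**: trajectories that exhaust the time budget carry
  τ = max_time with a censored flag; they are excluded from every
  statistic with a warning and block inference outright (a censored τ
  biases e^{−sτ} upward). The default budget is 100× a 50-trajectory
  pilot's crude mean.
- **Sample std** uses the n−1 denominator; the COV is therefore slightly
  biased at very small n.
- **Barriers**: 1-D, max of U on the segment between minima; 2-D, the
  minimax level found by bisection on sublevel-set connectivity of a dense
  grid (≤ 0.05 Å step where feasible) — robust to any path shape and
  oracle-checkable. Basin widths are curvature-based, σ = √(k_B T / U″).
- **Stationary points**: L-BFGS-B with analytic gradients plus a Newton
  polish on the gradient root; convergence demands |∇U| < 10⁻⁶ and
  duplicates merge within 10⁻³ Å.

## Problem sizes

The shipped test suite and the acceptance script run on one CPU core:
oracle-vs-identity checks use 5×10⁴ analytic samples, the extrapolation
benchmark 10⁴ samples at three reference rates (0.0005–0.002 ps⁻¹), the
drift-diffusion KS check 5000 Langevin trajectories, and the double-well
benchmark 2000 trajectories (with 1500-trajectory fixtures reused across
tests). These sizes hold every stochastic tolerance used (3 combined SE,
≤ 15% extrapolation error at the smallest r*) with comfortable margins
while keeping the whole suite in the minutes range.

## Known limitations

- Inference recovers the *mean* reset-free FPT, not the full distribution.
- The prediction only reaches r > r*; r < r* comes from polynomial
  extrapolation, whose error grows quickly with r* (the 500%-error regime
  at speedups ≳ 8 is reproduced by the benchmark, not hidden).
- The empirical transform degrades when (r − r*)·τ is large for most
  samples; the ESS guard avoids chasing noise there but also means very
  high candidate rates are simply not searched.
- Sharp-resetting ensembles cannot be used as inference input (by
  construction of the identity), only as a target protocol.
- The Langevin layer is single-particle and NVT-only; multi-particle
  systems, constraints and other ensembles are out of scope.
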