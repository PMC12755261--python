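# Methods

## Model

Each gene product is a continuous concentration x_i ≥ 0 evolving as a
piecewise-deterministic Markov process: while a gene is active, bursts
arrive as a Poisson process with rate k_i (min⁻¹) and add a random amount
b_i to x_i; between bursts the level obeys dx_i/dt = −γ x_i, with one
dilution rate γ (min⁻¹, the cell growth rate) shared by all genes.
Activation is a step function: gene i+1 has burst rate zero until x_i
first reaches its threshold X_i, and rate k_{i+1} afterwards. All genes
start at zero and gene 1 is active from t = 0. The first-passage time
(FPT) is the first instant x_N ≥ X_N.

Burst sizes come from one of four families with closed-form moments:
geometric on support {0, 1, 2, …} (the default; a mean-m draw has
⟨b²⟩ = m(2m+1), and means below one — needed for the reference
parameterization with ⟨b₂⟩ = 0.625 — are representable), geometric on
{1, 2, …} (⟨b²⟩ = m(2m−1); provided because published simulation values
sit between the two conventions' predictions and the support convention
is rarely stated), fixed, and exponential. Burst sizes add to a
continuous state; zero-size geometric bursts are legal no-op events.

Parameters that matter, with defaults used throughout the fixtures:
γ = 0.05 min⁻¹; geometric bursts of mean 4; steady states
x̄ = k⟨b⟩/γ of 800 or 1000; thresholds expressed as relative thresholds
α = X/x̄ ∈ (0,1). Genes may be declared by (x̄, ⟨b⟩) with k derived,
matching how published parameter sets are stated. All theory functions
also accept the dimensionless relative time γ⟨T⟩ directly.

## Simulation

Decay between bursts is integrated analytically (multiplication by
e^{−γΔt}), so the simulator is exact for the hybrid process — there is no
internal time step to converge. Because the level is non-increasing
between bursts, threshold crossings can only occur at burst instants;
detection compares inclusively (level ≥ X).

Under step activation each stage starts from level zero at its
activation instant, so per-stage crossing times are independent and the
default execution path simulates stages separately, vectorized across
replicates (finished replicates are compacted away; work is proportional
to the number of burst events actually drawn). A coupled mode runs the
merged Poisson process of all active genes on one global clock and exists
purely as a cross-check; the test suite verifies the two paths give
statistically indistinguishable total-FPT distributions (two-sample
Kolmogorov–Smirnov, n = 4000, 1% level).

Reproducibility: one root seed spawns an independent `SeedSequence` child
per stage; ensembles are bit-identical for a given (cascade, n, seed).
A per-replicate event cap (default 10⁷ bursts) guards parameter choices
whose crossing would effectively never happen; exceeding it raises an
explicit error rather than silently truncating. Ensemble summaries use
the plug-in estimator CV_T² = var(T)/mean(T)², with a delta-method
standard error computed from the sample's central moments up to order
four so that tests can set statistically justified tolerances.

## Moment dynamics

The generator of the PDMP yields closed ODEs for the first two moments of
an active gene: d⟨x⟩/dt = k⟨b⟩ − γ⟨x⟩ and
d⟨x²⟩/dt = k(2⟨x⟩⟨b⟩ + ⟨b²⟩) − 2γ⟨x²⟩. From zero initial conditions the
solutions are ⟨x⟩(t) = x̄(1−e^{−γt}) and
σ²(t) = (⟨b²⟩/2⟨b⟩)x̄(1−e^{−2γt}); the stationary noise is
CV² = ⟨b²⟩/(2⟨b⟩x̄), a function of burst statistics and steady state
only. Moments above order two are not exposed — nothing downstream needs
them. Downstream genes' transients are expressed in stage-local time
(the clock restarts at activation), consistent with the independence
decomposition; cross-gene covariances vanish under step activation.
`integrate_moments` re-solves the ODEs numerically (LSODA,
rtol 1e−10 / atol 1e−12) and is held to a sup-norm relative deviation
below 1e−6 from the closed forms, including a stiff case at γ = 50.

## Small-noise FPT theory

Timing fluctuations are linearized around the mean trajectory: the FPT
variance of one stage is the protein variance at the threshold divided by
the squared slope of the mean trajectory there. This gives the mean and
noise expressions quoted in the README. The approximation is good for
thresholds well inside (0,1) — the suite checks simulation agreement
within 25% for α ∈ [0.4, 0.7] — and overestimates the noise as α → 0 or
α → 1; at α = 1−e^{−2} ≈ 0.865 the formula gives 0.060 where simulation
gives ≈ 0.046.

The N-gene noise is implemented in the symmetric sum form; no stage is
singled out as the dependent variable, and the fixed-mean constraint is
checked rather than substituted. α = 0 is admitted (an unused gene
contributes nothing), so regime boundaries are representable. In the
two-gene α₂-parameterized form, α₂ exactly at the upper bound
1−e^{−γ⟨T⟩} is rejected: the mean constraint would force α₁ = 0 with
log-singular sensitivity.

## Threshold optimization

Minimizing CV_T² at fixed γ⟨T⟩ gives α_n* = 1 − e^{−γ⟨T⟩/N}·CV_n/GM(CV)
(GM over all N genes, the evaluated gene included — the N = 2 reduction
to the interval e^{−γ⟨T⟩} < CV₂/CV₁ < e^{γ⟨T⟩} confirms this reading).
At the optimum CV_i/(1−α_i*) is constant across genes. A gene whose
ratio to the geometric mean leaves the interval
(e^{−(N−1)γ⟨T⟩/N}, e^{γ⟨T⟩/N}) cannot hold a feasible threshold.
The exclusion procedure is iterative: drop the noisiest gene violating
the upper bound and re-solve on the remainder. This suffices because the
log-ratios to the geometric mean sum to zero, so any lower-bound
violation implies an upper-bound violation elsewhere; the least-noisy
gene always survives. Boundary ties classify as the adjacent single-gene
regime, where the coupled formulas yield α = 0, so the optimum is
continuous across regime boundaries.

For identical genes the optimum splits the time evenly,
α* = 1−e^{−γ⟨T⟩/N}, and relaxing the fixed mean gives the per-stage
stationarity condition (1−x)e^{2x} = 1. The root is found by Brent's
method on (10⁻⁹, 1−10⁻⁹) to xtol 1e−14; uniqueness follows from the
derivative e^{2x}(1−2x), which makes the function rise then fall with a
single interior sign change. The minimum noise evaluates algebraically to
CV₁²/(N x*(1−x*)) ≈ 6.177·CV₁²/N at the full-precision root; the
conventional three-decimal rounding x* = 0.797 gives the familiar 6.181
prefactor, and the library returns full precision.

## Synthetic-data fixtures and what passing tests show

The experiment fixtures (`fig2_inset` … `fig6`) pin the published
parameter sets: γ = 0.05 min⁻¹; geometric bursts of mean 4 (plus 0.625
and 17.5 for the two-gene regime sweep, giving noise ratios 0.5/1.0/2.0);
steady states 800 and 1000; mean FPTs of 10 and 40 min; replicate counts
of 10⁵ or 2×10⁵ per point. Desk-scale runs default to 10⁴ replicates
(the `--full` CLI flag restores published counts); the acceptance script
uses 10⁵ replicates for the Monte-Carlo targets, which resolves CV_T² to
a relative standard error of about 0.5%.

The generator emulates intrinsic noise only: bursty production plus
first-order dilution. It deliberately omits extrinsic sources —
growth-rate variability, resource sharing, cell-cycle effects — as well
as graded (Hill-type) activation, spontaneous degradation distinct from
dilution, and discrete copy-number effects at very low thresholds.
Passing tests therefore certify the intrinsic-noise floor of cascade
timing, not the full variability of real single-cell measurements, where
extrinsic noise often dominates and correlates stages.

## Numerical and design choices

- Geometric support {0,1,…} is the default because the reference
  two-gene sweep requires a burst mean of 0.625; the {1,2,…} sampler is
  available as `geometric_shifted`. Published simulated noise values at
  high thresholds fall a few percent below both convention's small-noise
  predictions, consistent with the approximation's known bias.
- Monte-Carlo tolerances in tests are set in units of the estimator's
  standard error (3–4 SE) or as the documented accuracy band of the
  small-noise approximation (25% mid-range), never tuned to a specific
  draw.
- The optimizer's global optimality is spot-checked against 1000 random
  threshold vectors satisfying the same mean constraint (Dirichlet splits
  of the log-time budget) for 20 random parameter draws.
- Degenerate inputs: thresholds at or above steady state warn (crossing
  still almost sure, but slow and outside the theory's validity);
  α outside [0,1) in theory functions raises; an empty cascade or
  non-positive rate raises at construction.

## Known limitations

The stage-local small-noise theory evaluates the threshold-crossing slope
in each stage's own clock; for strongly overlapping stages under graded
activation this would not be exact, but under step activation it is. The
simulator's stage decomposition is exact only for step activation — a
Hill-function variant would need the coupled path as the primary engine.
Mean-FPT predictions carry the documented bias at extreme thresholds
(overestimating the mean for α near 0); exact FPT densities are out of
scope.
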