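# Methods

This note documents the models, numerical choices and design decisions
behind `devsens`, and what the synthetic-data scenarios do and do not
emulate.

## Developmental model

Development is an initial-value problem dx/dt = f(t, x, λ), x(t0) = x0,
with smooth f. The built-in model is a two-gene toggle switch:

    dx1/dt = (2 + λ1)/(1 + x2²)²        − 0.4 x1
    dx2/dt = (2 + λ2)/(1 + x1³ + λ3)²   − 0.4 x2

x1, x2 are expression levels of two mutually repressive genes; λ1 and λ2
modulate the regulatory input each gene receives and are genetically
determined in the population scenarios; λ3 (zero unless the environmental
variant of the model is requested) shifts the repression of gene 2 and is
drawn per individual from an environmental distribution. At the reference
λ* = (0, 0, 0) the system is bistable: stable states near (5.0, 3×10⁻⁴)
(gene 1 ON) and (0.0074, 5.0) (gene 2 ON), separated by a saddle near
(1.05, 1.09).

The initial condition defaults to x0 = (0, 0), from which the reference
trajectory settles into the gene-2-ON state by developmental time ~20. x0
is configurable; all parameters of the algebraic form (basal input 2, decay
0.4, Hill exponents 2 and 3, outer square) are collected in
`ToggleSwitchParams`, and the λ3 substitution (x1³ → x1³ + λ3 inside the
squared denominator) is confined to the one factory `toggle_switch` so the
parse can be revised in a single place.

## Integration

Trajectories are integrated with an adaptive RK45 at rtol 1e-8 /
atol 1e-10 (sensitivities amplify solver error, hence the tight defaults),
restarted at every output grid point. Segment-wise restarting makes an
uninterrupted run identical to a run that is paused at grid points, which
is how the population simulator injects developmental noise.

Populations are integrated as one stacked vector field (a single adaptive
solve for all individuals per unit step) for speed. Within a step, rows
with identical (state, parameters) are collapsed and solved once: identical
ODEs have identical solutions, and this guarantees that a clone population
with noise off is bit-identical to the single-trajectory integrator. The
scalar right-hand side delegates to the vectorized implementation so both
paths use the same floating-point operations.

## Sensitivities

Three routes, agreeing pairwise to ≲1e-3 relative on the toggle switch for
t ∈ [1, 50]:

* **Variational**: the n + n·p augmented system (state plus all sensitivity
  columns) integrated jointly; Jacobians analytic when supplied, otherwise
  central finite differences of f (step 1e-6, relative).
* **Finite differences**: central differences of trajectories,
  default Δλ = 1e-4 (chosen by a step-halving convergence check; halving
  to 5e-5 moves the result by <1e-4 relative).
* **Regression**: per time and trait, OLS of simulator output on parameter
  offsets, for black-box models with no accessible f.

Second derivatives s⁽¹⁾(t) use the central second difference with
Δλ = 1e-3 and tighter solver tolerances (1e-10/1e-12), because the second
difference divides solver error by Δλ².

Sensitivities all start at the zero vector, so t0 is excluded from every
relative comparison and angle computation.

Angles between vectors are computed with the atan2 form (norm of the
orthogonal component against the dot product), which keeps precision for
nearly collinear vectors where arccos saturates. Two conventions are
exposed: directed [0°, 180°] (default for sensitivity vectors) and axial
[0°, 90°] (for sign-ambiguous directions: eigenvectors, response vectors).
The random-angle null — density ∝ sin^(d−2)θ in trait-space dimension d —
is provided with closed-form pdf/cdf via the regularized incomplete beta
function.

## Genetic architecture

Each biallelic locus targets one developmental parameter and shifts it
additively by γ per B allele; genotypes are coded (B count − 1) ∈
{−1, 0, +1}, so the all-heterozygote individual sits exactly at λ* and the
regression slope of phenotype on code is the average effect with the sign
convention α ≈ +s(t)γ. All nonlinearity (dominance at the trait level)
arises in the parameter → phenotype map.

With q the frequency of B and exact Hardy–Weinberg weights, the OLS slope
equals a(t) + d(t)(p − q). We verified this identity against an
independent frequency-weighted regression oracle (exact HW counts at
q = 0.3, agreement to 1e-10 at every time point) and use this form for
`EffectCurves.alpha`; textbook statements of the dominance weight differ in
sign depending on which allele's frequency is called p. At q = 0.5 — the
setting of all headline scenarios — the dominance term vanishes and
α(t) = a(t) exactly.

## Synthetic populations

`simulate_population` maps genotypes (plus per-individual environmental
draws) to parameters, develops everyone jointly, and applies two noises:

* **Developmental noise**: after each unit step, independent Gaussian
  perturbations per state with SD = dev_sd_rel × |current state|. The
  perturbed state seeds the next step, so noise propagates through the
  remaining dynamics and accumulates temporal correlations. Relative-to-
  current-state scaling (rather than to a fixed reference value) is a
  deliberate reading of "noise as a percentage of trait value"; it is the
  more demanding choice because the OFF gene's small values keep its noise
  proportionally small. Negative states are allowed (the dynamics are
  defined for them); occurrences below −1 are logged.
* **Measurement noise**: Gaussian, SD = meas_sd_rel × |state|, applied
  to the recorded values only.

What the generator does *not* emulate: intrinsic molecular stochasticity
with realistic autocorrelation (noise is injected only at unit-step
boundaries), linkage, epistatic parameter maps, relatedness, or
genotype-environment correlation. Passing benchmarks therefore show that
the estimators exploit developmental memory under idealized sampling, not
that they are robust to confounded real data.

Scenarios (defaults are the study conditions):

* `scenario_single_locus`: 20 individuals, one locus on λ1, q = 0.5 at
  *exact* HW counts (5/10/5) so the noise-free regression is
  deterministic; γ = 0.01; trait = gene-1 expression.
* `scenario_estimation`: 10 loci per genetic parameter at q = 0.5,
  γ ~ N(0, 0.01²) redrawn per replicate; measurement noise 1–8% and
  developmental noise 1–20% of trait value; population sizes 64–4096.
* `scenario_alignment`: 5,000 individuals (2,000 in scaled-down runs),
  10 loci on λ1 at q = 0.5, 10 loci on λ2 at minor allele frequency
  ∈ {0.001, 0.016, 0.5}, γ ~ N(0, (10⁻⁴)²), environmental λ3 ~
  N(0, (1.5×10⁻³)²), development to t = 50, no other noise.

## Estimators

The static estimator fits y(t) = μ(t)1 + Zα(t) + ε(t) independently at
each time by OLS (the design is constant over time, so its pseudoinverse is
factored once). The dynamic estimator runs one scalar Kalman filter per
locus over the static estimates with the random-walk model
α(t) = α(t−1) + η, η ~ N(0, Q):

* Observation variance R_t: the OLS sampling variance of the slope at time
  t (configurable to a fixed value).
* Process variance Q: per locus, a method-of-moments plug-in —
  median((Δα̂ˢ)²) minus twice the median observation variance (the part of
  the squared first differences explained by sampling noise), floored at
  1% of the raw median so the filter never degenerates to a constant
  model. The subtraction matters: the raw median-of-differences
  systematically overestimates Q when the static estimates are noisy,
  making the filter under-smooth exactly where smoothing helps most.
* Initialization: mean 0, variance 1e-12 — the sensitivity, and hence the
  true average effect, is exactly zero at t0.
* Forward filtering only by default (each estimate uses the history up to
  t); an RTS smoothing pass is available behind `KalmanConfig(smooth=True)`.

The benchmark error metric is |α̂ᵢ(t) − γᵢ s(t)| / |γᵢ s(t)| on the gene-1
trait, averaged over loci and t ≥ 1. It is heavy-tailed by construction:
loci with |γᵢ| near zero and late times (where s on the gene-1 trait is
~4×10⁻³) produce large relative errors, which is precisely the regime where
filtering pays off.

## Covariance matrices and proportionality

G(t) = Σᵢ 2pᵢqᵢγᵢ² s_{w(i)} s_{w(i)}ᵀ from the nominal architecture
(`empirical_G` offers the realized-frequency variant), E(t) = Σⱼ σⱼ²
s_{v(j)} s_{v(j)}ᵀ, P = G + E. The proportionality diagnostic is the axial
angle between leading eigenvectors (Gmax, Pmax), with eigenvector sign
fixed by making the largest-magnitude component positive; a numerically
tied leading eigenvalue raises an error rather than reporting an arbitrary
axis. For the two-trait switch the single angle is the natural diagnostic;
fuller subspace comparisons for higher-dimensional trait spaces are out of
scope.

In the alignment scenario the λ2 and λ3 forcing vectors act on the same
gene, so their sensitivity vectors are collinear throughout development
(axial angle < 1°) — the developmental condition for G–P proportionality is
built in — and the G–P angle is governed purely by how much variance the
λ2 loci carry (the population condition): the median angle falls
monotonically (roughly ∝ 1/(2pq)) as the minor allele frequency rises from
0.001 to 0.5. A caveat discovered in this implementation: because the
reference trajectory sits at the gene-2-ON attractor at t = 50, the λ1
sensitivity norm is ~700× smaller than λ2's, so G is λ2-dominated at every
frequency and the angles, while strictly ordered, are microscopically small
(10⁻⁴–10⁻⁶ degrees).

## Selection experiment

Truncation selection keeps the 50% of individuals whose final-time
phenotype is closest (Euclidean) to the optimum (4, 4); survivors are
paired randomly and monogamously; each pair produces 4 offspring by
independent Mendelian segregation (allele pairs are stored explicitly, so
segregation from heterozygotes is exact); offspring develop with fresh
environmental draws. The selection differential S and the observed response
are measured against the full pre-selection parental mean. Predictions:
Δz_G = G β with β = P⁻¹S, where G is the architecture-derived matrix at
t_end and P is the empirical phenotypic covariance of the parental
generation; the P-proxy prediction is P β = S identically.

Known limitation (same geometry as above): with effect SD 10⁻⁴ against
environmental SD 1.5×10⁻³ on collinear sensitivity directions, the
phenotype distribution, S, and the realized response all lie along the
λ3 axis; the P-proxy is then aligned with the observed change by
construction, and the G-based prediction is degraded by inverting the
nearly rank-1 empirical P. The acceptance test encoding the expectation
that G should beat the P-proxy at low allele frequency documents this and
fails under these study conditions; the mechanism is analyzed in the test
and above. The deterministic response (~2×10⁻⁵ in trait units) is also an
order of magnitude below the environmental resampling noise of the
offspring mean, even at 5,000 individuals.

## Problem sizes and determinism

Default experiment sizes (population 64–512 with 100 replicates per
benchmark cell; 2,000 individuals × 20 seeds for selection; 10⁴ draws for
the Monte-Carlo covariance check; 10⁵ samples for the angle null) complete
in about two minutes total; `--full-scale` switches to the full sizes.
Every stochastic stage takes an explicit seed (numpy Generator);
re-running any stage or CLI command with the same config reproduces every
numeric artifact byte for byte.
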