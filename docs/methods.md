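# Methods

## Response model and hypotheses

The package models a continuous endpoint (e.g. log change in circulating
tumor DNA, where decreases are good) for a patient with biomarker profile
x ∈ {0,1}^L receiving one of K experimental treatments or control:

    y = f(x, T)'θ + ε,   ε ~ N(0, σ²),
    θ = (α, β_1..β_K, γ_1..γ_L, δ_11, …, δ_KL),

with feature map f = (1, T_1..T_K, x_1..x_L, x_l·T_k …). α is the control
mean in the all-negative subgroup, β_k a treatment main effect, γ_l a
prognostic biomarker effect and δ_kl a predictive treatment-by-biomarker
interaction; the interaction ordering is treatment-major (δ_11, δ_12, δ_21,
δ_22 for K = L = 2). There is no biomarker–biomarker interaction term, so
the model is not saturated: subgroups share information through the common
parameters. The (K+1)·2^L biomarker–treatment combinations are enumerated
profile-major with control first; design measures, schemes and tables all
use this order.

The 2^L·K candidate hypotheses are the treatment-versus-control effects
c_r'θ = β_k + Σ_{l∈S} δ_kl, one per treatment k and biomarker subset S,
ordered treatment-major with subsets in binary order. Tests are one-sided
lower (benefit = negative) Wald tests at level α′ using the standard-normal
critical value with the residual-variance estimate σ̂² = RSS/(n−p) plugged
into cov(θ̂) = σ̂²(X'X)⁻¹; a normal rather than t quantile is used
deliberately, since at confirmatory sample sizes (hundreds of residual
degrees of freedom) the difference is negligible.

## Bayesian screen

(θ, σ²) gets a conjugate normal-inverse-gamma prior NIG(θ₀, V₀, a, b),
meaning θ | σ² ~ N(θ₀, σ²V₀) and σ² ~ IG(a, b). The posterior after n_II
phase II observations is NIG(θ_m*, V*, a*, b*) with

    V*   = (V₀⁻¹ + X₀'X₀)⁻¹
    θ_m* = V* (V₀⁻¹θ₀ + X₀'y)
    a*   = a + n_II/2
    b*   = b + (θ₀'V₀⁻¹θ₀ + y'y − θ_m*'(V*)⁻¹θ_m*)/2,

and θ's marginal is multivariate Student-t with 2a* degrees of freedom and
scale Σ* = (b*/a*)V*. The hypothesis probability P_r = P(c_r'θ < τ_r) is
computed by default from the exact univariate Student-t CDF of c_r'θ — a
draw-based Monte Carlo mode (`method="mc"`) and a large-df normal
approximation (`method="normal"`) are retained, and the exact and MC modes
agree within binomial error by construction. The default prior is vague
(a = b = 10⁻⁴, unit prior scale); the worked example's prior puts a mildly
negative mean (−0.1) and doubled variance on the two linked interactions,
encoding "the linked treatments probably help, but we are unsure".

Patients (response paired with its covariate row) are resampled with
replacement B times; E(P_r) is the mean over replications, and
w_r = E(P_r)·1{E(P_r) ≥ κ}. κ and τ may be scalars or per-hypothesis
vectors; κ = 0 makes selection a no-op (every subgroup enrolled, full model
analyzed — the randomized-controlled-trial limit of the framework). The
weights intentionally do not sum to one: only their ratios matter for the
optimum, and scaling them all by a constant provably leaves the argmin
unchanged (tested). The bootstrap also averages the posterior mean of θ
across replications; that average is the default "assumed truth" for the
downstream evaluation stage.

## Model reduction

Enrolling only the selected hypotheses' subgroups (each contributes its
control cell and its tested-treatment cell) can make the full model
non-identifiable. `reduce_model` drops parameters whose design column is
identically zero on the enrolled support and merges parameters whose
columns coincide (a β_k administered only where some x_l = 1 is confounded
with δ_kl; the merged parameter β_k′ records the combination it estimates).
For identical-column confounding this characterizes estimability exactly: a
contrast is expressible in the reduced model iff its coefficients vanish on
dropped terms and are constant within each merge group; anything else
raises a `NonEstimableError` rather than silently reporting a biased
estimate. Merged substitution records are also used in the opposite
direction: the simulator classifies hypotheses as false/true nulls by the
exact contrast value in full-model coordinates, never in the reduced
parameterization.

## Design criterion and solver

The weighted L-optimality criterion Φ(p) = Σ_r w_r c_r'M(p)⁻¹c_r with
M(p) = n Σ_i p_i f_i f_i' is convex in p (each summand is a matrix-fractional
function), so any local optimum on the simplex is global; n is a pure scale
factor and defaults to 1. Minimization uses SLSQP on log Φ — the same
minimizer, but the logarithm tames the criterion's enormous dynamic range
near the boundary of the simplex, where raw-scale line searches were
observed to stall at false optima from random starts. Each solve uses
multi-start (equal allocation plus Dirichlet(1) draws, default 5 starts)
with restart-on-stall, reports the across-start objective spread as a
uniqueness diagnostic (observed ≤ 10⁻¹¹ on the shipped problems), clips
proportions below 10⁻⁶ to exact zeros and renormalizes. Excluded design
points (combinations not enrolled) are held at exactly zero rather than
penalized. A singular information matrix en route returns a large finite
penalty (10¹⁵) so the optimizer backs away; no ridge is ever added, because
a ridge would silently make non-estimable contrasts look estimable.

The optimal measure is converted to per-subgroup randomization
probabilities by renormalizing within each biomarker profile; a profile
with total mass below 10⁻⁶ is marked not enrolled. The criterion does not
constrain across-subgroup mass to the biomarker prevalences — prevalence
enters only the simulation stage, and only the within-subgroup ratios
survive the conversion. Comparators: ξ_rct randomizes every subgroup
equally across all K+1 arms; ξ_tlt offers each subgroup control plus the
treatments whose linked biomarker it carries (all arms when it carries
none).

## Simulation engine

`ConfirmatoryTrial.simulate(n_bio, n_alloc)` uses the nested plan: draw
subgroup sizes from a multinomial over the enrolled profiles (probabilities
proportional to the prevalence products), then for each profile draw
n_alloc independent treatment allocations and responses. Within a
replicate the least-squares fit is computed from per-cell sufficient
statistics (cell counts, cell response sums, total sum of squares) — the
responses themselves are simulated patient-by-patient, so this is
algebraically identical to assembling the n × p design matrix, just faster;
a dedicated test cross-validates the engine against an explicit
patient-level statsmodels OLS path. Rank-deficient replicates are dropped
and counted, with a warning escalated in the summary above 1% (with
n = 1000 and the shipped schemes this never triggers). Total n applies to
enrolled patients; subgroups a scheme does not enroll are simply not
recruited. ENCR is defined as the sum of rejection rates over hypotheses
whose true contrast value is negative, so it equals the sum of the reported
powers exactly.

`analytic_power` provides an independent closed-form cross-check: with
M₁ = E[f f'] the expected per-patient information under prevalence and
scheme, the rejection probability is Φ(−z_α′ − c'θ / √(σ² c'M₁⁻¹c / n)).
Simulated and analytic powers agree within ±0.02 at 10⁴ replicates on every
shipped configuration (tested); the approximation ignores σ̂²-estimation
noise and subgroup-size variation, both negligible at n = 1000.

## Default study conditions

The worked example fixes: K = L = 2; biomarker prevalences 0.3 each
(independent); phase II n_II = 400 with equal randomization; confirmatory
n = 1000; σ² = 1.15; α′ = 0.05; τ_r = 0; κ = 0.5; B = 10 000 bootstrap
replications; 100 × 100 nested replications for operating characteristics
(the acceptance script uses 200 × 200 to shrink Monte Carlo noise on its
two headline ENCR values; each 10⁴-replicate evaluation takes about a
second). The example's phase II and confirmatory parameter vectors live in
`stratdesign.presets` as explicit label→value maps, with the interactions
assigned treatment-major (δ₁₂ = the effect of treatment 1 in
biomarker-2-positives); the confirmatory vector is the bootstrap-averaged
posterior mean of the phase II realization, and `theta_flat_effects` builds
the summary-statistics scenario in which the four selected hypotheses all
have true effect −0.2 while the non-selected ones stay positive.

## What the generator does and does not emulate

Synthetic patients have exactly independent Bernoulli biomarkers, exactly
linear mean structure and homoscedastic Gaussian noise — the model's own
assumptions. Passing tests therefore demonstrate the internal correctness
and calibration of the machinery (nominal Type I error, solver optimality,
estimability bookkeeping), not robustness to model misspecification:
correlated biomarkers, non-normal or heteroscedastic endpoints,
higher-order interactions and population drift between phases are all
outside what the simulations can certify. Other known limitations, shared
with the framework itself: no multiplicity adjustment across the retained
hypotheses (the tests share information through the common model and are
not independent), no interim analyses, no sample-size search, and a
screening stage whose E(P_r) values inherit the sampling noise of the one
phase II realization they are computed from — two labs running the same
pipeline on different phase II draws will select different hypotheses with
non-trivial probability, which is why the seed is mandatory and every
report records it.

## Numerical choices

Posterior updates use Cholesky factorizations of the (symmetrized)
precision; V₀ must be positive definite, which also guarantees every
bootstrap update is well-posed. Design measures must sum to 1 within 10⁻⁹.
Randomization probabilities per enrolled subgroup sum to 1 exactly by
construction. Degenerate inputs fail loudly: zero contrast variance, empty
phase II data, a scheme enrolling no subgroup, n below the parameter count,
and infeasible support exclusions all raise informative errors. All
randomness flows from `numpy.random.Generator`; the pipeline spawns
per-stage child streams from the single mandatory seed, so adding a
comparator scheme never perturbs the earlier stages, and fixed-seed runs
are byte-reproducible (tested).
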