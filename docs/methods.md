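# Methods

`otmaxent` computes maximum-entropy reweightings of an empirical distribution
under a squared 2-Wasserstein (W2²) proximity constraint to a parametric
target law, and packages three applications of that primitive: semi-parametric
inference for complex surveys, demographic parity in regression, and
distribution-guided portfolio allocation.  This note records the model, the
numerical choices, and the places where the design was genuinely open.

## The core reweighting problem

Given atoms s₁,…,sₙ, the weighted empirical distribution is Σᵢ wᵢ δ_{sᵢ} with
w on the probability simplex.  The primal problem is

    max_w  Hₙ(w)   subject to   W2²(Σᵢ wᵢ δ_{sᵢ}, f_θ) ≤ ε
                                 (and optionally Σᵢ wᵢ g(sᵢ, θ) = 0),

with Hₙ(w) = −Σ wᵢ log wᵢ in nats, and the penalized (dual) form
max_w Hₙ(w) − λ·W2²(·, f_θ).  In one dimension
W2²(p, q) = ∫₀¹ (F_p⁻¹(u) − F_q⁻¹(u))² du, the squared L² distance between
quantile functions.  For a discrete p with sorted atoms x₍ₖ₎ and cumulative
weights cₖ this is evaluated segment-exactly:

    W2² = Σₖ [ x₍ₖ₎² (cₖ − cₖ₋₁) − 2 x₍ₖ₎ (G1(cₖ) − G1(cₖ₋₁)) ] + E_q[X²],

where G1(c) = ∫₀ᶜ F_q⁻¹(u) du is available in closed form for the normal and
skew-normal targets (via their partial expectations) and piecewise-linearly
for a discrete target.  The expression is smooth in the cumulative weights
with gradient ∂W2²/∂cₖ = (x₍ₖ₎ − x₍ₖ₊₁₎)(x₍ₖ₎ + x₍ₖ₊₁₎ − 2 F_q⁻¹(cₖ)),
which is what makes first-order simplex methods effective.  The reporting
function `w2sq_to_target` defaults instead to a midpoint quadrature on
n_quad = 512 quantile levels (deterministic, adequate for diagnostics); the
segment-exact path is used inside every solver and available for validation.

**Solver.** The penalized problem is concave (W2² is convex in w), and is
solved by entropic mirror ascent with Armijo backtracking.  Equality moment
constraints are maintained exactly at every iterate by an exponential tilt
(a small Newton solve), so iterates remain on the intersection of the simplex
with the moment hyperplane.  Numerical choices: weights floored at 1e-12 to
keep the entropy term differentiable; uniform-weight initialization; a
first-order KKT residual certified to ≤ 1e-7 at the solution; a multi-start
fallback (5 Dirichlet(1) starts under a fixed seed) if certification fails;
equal atoms are kept in stable input order (they may exchange weight without
changing any objective, so the canonical solution from the stable sort is
reported).  The constrained form is solved by bisection/bracketing on λ until
the constraint is active within a relative tolerance of 1e-4, or slack at
λ = 0 (in which case the tilted-uniform solution is returned).  Exposing both
the ε-form and the λ-form is deliberate: the ε-form is interpretable, the
λ-form is cheap, and the bisection ties them together (the reported `lam` of
a constrained solve reproduces the same weights when passed to the penalized
solver).

**ETEL.** Under moment conditions only, the exponentially tilted empirical
likelihood has the closed form wᵢ*(θ) ∝ exp(πᵢ λ(θ)ᵀ g(xᵢ, θ)) with the tilt
λ(θ) found by minimizing n⁻¹ Σ exp(πᵢ ηᵀ g(xᵢ, θ)) (damped Newton with line
search).  When the convex hull of the g(xᵢ, θ) does not contain the origin
the likelihood is zero; the implementation returns −∞ for the log-likelihood
(checked by sign inspection for scalar g, linear programming otherwise).

## Target distributions

The normal and skew-normal SN(ζ, ω, α) families are wrapped over
`scipy.stats`.  The skew-normal density is (2/ω) φ((z−ζ)/ω) Φ(α(z−ζ)/ω);
α = 0 recovers the normal.  With δ = α/√(1+α²): mean = ζ + ωδ√(2/π),
variance = ω²(1 − 2δ²/π), and the standard skewness expression, giving the
skewness bound |γ| < 0.9952717.  Moment matching inverts this chain: δ by
bracketed root-finding on the (strictly monotone) skewness map, then ω and ζ
in closed form.  Quantiles refine scipy's inversion with up to three Newton
steps on the CDF (the far tail of a strongly slanted law is otherwise only
~1e-7 accurate).  The partial expectation E[X; X ≤ q] used by the W2
machinery is closed-form for both families; for the standard skew normal,
E[U; U ≤ t] = −2φ(t)Φ(αt) + δ√(2/π)·Φ(t√(1+α²)).

Sign convention: α > 0 implies positive (right) skewness.  This is the
standard parameterization; prose claiming that positive slant gives a
left-skewed law is an erratum relative to the formulas above and is not
followed.

## Survey inference

`SurveyData` carries observations and strictly positive weights, canonically
rescaled to sum to n.  The normal-family PMLE is closed-form
(μ̂ = Σπᵢxᵢ/n, σ̂² = Σπᵢ(xᵢ−μ̂)²/n); its variance is the design-consistent
sandwich H⁻¹VH⁻¹/n where H is the weighted average Hessian of the
log-density and V the outer product of the *weighted* scores πᵢsᵢ (Binder's
linearization; with unit weights both reduce to the information matrix and
the PMLE to the MLE, which instead reports the naive inverse-information
variance so that its undercoverage under informative selection is visible).
A logistic family (weighted GLM via statsmodels, same sandwich) supports
health-survey-style binary outcomes; for binary data only moment/score
constraints are meaningful, so no distributional W2 constraint is offered
there.

**Weighted FPBB.** Pseudo-populations of size N are reconstructed by the
weighted finite-population Bayesian bootstrap: every sampled unit enters
once, and the remaining N − n slots are filled by a Pólya urn whose initial
masses are the expansion-scale weights minus one, N πᵢ/n − 1, with constant
reinforcement c = (N − n)/n.  Two details are reconstructions (the procedure
is cited, not specified, in the source literature this follows): (i) the urn
masses must use expansion-scale weights — with weights summing to n the
initial masses would sum to zero — and weights below the scale floor are
clipped at one copy with a logged warning; (ii) a Pólya urn with constant
reinforcement is exchangeable with a Dirichlet-multinomial with
αᵢ = massᵢ/c, which is how counts are sampled (exact, O(n), and gives
E[countᵢ] = N πᵢ/n); a literal sequential urn is kept for cross-checks.

**BDCM.** For each of M pseudo-populations, an i.i.d. pseudo-sample of size n
is drawn (uniform with replacement) and θ = (μ, σ²) is profiled by maximizing
the ETEL subject to the mean moment condition g(x, μ) = x − μ and
W2²(Σwᵢδ_{xᵢ*}, N(μ, σ²)) ≤ ε.  ε = "auto" sets, per pseudo-sample,
ε = W2²(uniform weights on the pseudo-sample, N(θ̂_PMLE)) with θ̂_PMLE from
the original weighted sample — the calibration that makes the constraint
comparable to the PMLE fit.  The inner solve first computes the closed-form
moment-only tilt; only when its W2² exceeds ε does it switch to the KKT fixed
point w ∝ exp(η g − λ ∂W2²/∂w) (damped, in log space, 12 iterations) with λ
driven to the active constraint by a bracketed secant (relative tolerance
1e-3 — looser than the core solver because the profile optimizer only needs
the likelihood value to ~1e-4) warm-started across profile evaluations.
When even the entropy-free limit of the penalized path cannot reach ε at a
candidate θ the feasible set is empty and the likelihood is zero; the
profile evaluation then returns a large finite surrogate sloped in the
constraint violation, which steers the optimizer back toward the feasible
region without the non-finite arithmetic a literal log 0 would cause.  The
outer profile is Nelder–Mead over (μ, log σ²), at most 200 iterations,
initialized at the pseudo-sample ML fit; when the constraints are slack the
profile is flat in σ², and the initialization is then the natural reported
value.  The M estimates are combined as: point = mean, variance =
between-replicate variance × (1 + 1/M) (a Rubin-style inflation), normal
intervals; a percentile combination is available behind a flag.  Replicates
whose optimizer fails are dropped with a warning; more than 20% dropped is a
hard error.

**The simulation design.** The generator draws (X, Z) bivariate normal with
mean (0, 10), variances (4, 16) and correlation ρ; the inclusion score is
π* = Φ(β₀ + β₁ z) with β = (0.1, −1.8) applied to the *standardized*
selection variable z = (Z − μ_z)/σ_z.  Standardization is a deliberate
design choice: applied to raw Z the probit argument has mean −17.9 and
standard deviation 7.2, the relative inclusion scores span hundreds of
orders of magnitude, and selection degenerates into "take the n smallest-Z
units" — a regime in which no weighted estimator is meaningful.  Samples of
size n are drawn without replacement with probability proportional to π*
via an exponential race on the log scale (keys log Eᵢ − log π*ᵢ, exact under
arbitrarily small scores); Efraimidis–Spirakis keys are the equivalent
formulation.  Weights are 1/π*, normalized to sum 1 and rescaled to n; Z is
never exposed to the estimators.

The Monte-Carlo report for each (estimator, n, ρ) cell contains the average
norm bias ‖(μ, σ) − (μ̂, σ̂)‖ — on the (mean, standard deviation) scale, the
scale on which the three estimators' errors are commensurable — and a
coverage number defined as the average of the per-parameter coverages of the
nominal-95% intervals for μ and σ² (per-parameter coverages are also
reported).  Both definitions are package conventions; alternatives (variance
scale, single-parameter coverage) are easily derived from the per-replicate
fits.

A property of this design worth knowing: at strong selection (|ρ| large and
β₁σ_z-scale tilts), the inverse-probit weights are heavy-tailed — sampled
units in the thin-selection tail carry weights in the hundreds — so
inverse-probability-weighted estimators are nearly unbiased but noisy, and
sandwich intervals undercover because the realized sample often contains no
unit from the dominant-weight region.  The BDCM inherits this through the
FPBB, which resamples only observed units.  This is a statement about the
estimand/design pair, not a solver artifact; it is visible directly in the
simulation harness output.

## Demographic parity

Group-S fitted values get the uniform ECDF; group-T fitted values get a
weighted ECDF with simplex weights w.  Parity is measured by W2² between the
two.  The two-step scheme fits each group by OLS (pooled σ² = total SSE/n)
and then solves the weights-only problem
max_w −(1−λ★)·W2² − λ★·Σw log w.  The in-model scheme maximizes the joint
objective — group-S loss averaged by 1/n_S, group-T losses weighted by w,
parity penalty, entropy reward, with losses lᵢ = (yᵢ−h(xᵢ))²/2σ² — by
block-coordinate ascent initialized at the two-step fit: θ_S by OLS, θ_T by
w-weighted least squares, a joint backtracked gradient step on (θ_S, θ_T)
(the least-squares blocks ignore the parity term; the gradient step, using
the atom-gradient ∂W2²/∂h₍ₖ₎ = 2(h₍ₖ₎Δcₖ − ΔG1ₖ), is what lets the fits
themselves move the two ECDFs together), σ² profiled as the pooled weighted
mean squared residual, and the weight subproblem through the core solver.
Every block is backtracked toward its candidate so the objective never
decreases; sweeps stop when the objective changes by < 1e-8 (relative) or
after 500 sweeps.  Two literal-reading choices are documented rather than
"fixed": the S-loss is divided by n_S while the T-loss is weight-summed
(weights sum to one, so the scales are comparable), and σ² is shared across
groups.  Because the w-subproblem keeps the loss coupling of the joint
objective, the pure-entropy limit λ★ = 1 yields w ∝ exp(−lᵢ) rather than
exactly uniform weights; the two-step scheme's weight problem has no loss
coupling and does return uniform weights at λ★ = 1.

Fair prediction at a new group-T point is Nadaraya–Watson over the T
training points with a Gaussian kernel on covariate distance, Silverman's
rule bandwidth (1.06·s·n_T^(−1/5) with s the average per-coordinate sd), and
kernel weights multiplied by the parity weights; group-S predictions are the
linear fit and ignore the weights.  Protected attributes with more than two
levels are out of scope.

## Portfolio allocation

Sample moments are population-style (divide by n).  The mean-variance
baseline solves the simplex-constrained quadratic program (long-only, per
the portfolio definition used throughout); near-singular covariances get a
1e-10 ridge with a warning.  The moment-constrained maximum-entropy
allocator maximizes H_d(w) under w'μ ≥ μ₀ and w'Σw ≤ σ₀², with feasibility
pre-checked (the attainable mean range under the variance cap is reported on
infeasibility).  The distribution-guided allocator minimizes

    (1 − λ★) · W2²( n⁻¹ Σᵢ δ_{w'R(i)}, f_θ₀ ) − λ★ · b_d · H_d(w),
    b_d = 1/log d  (so b_d·H_d(w) ∈ [0, 1]),

where the atoms w'R(i) move with w while the atom weights stay uniform —
the reverse of the core problem, which makes the objective nonconvex and
piecewise-smooth through the sort of portfolio returns.  It is solved by
SLSQP from 10 fixed-seed Dirichlet starts plus the uniform start, with the
segment-exact W2² and its chain-rule gradient through the sorted returns;
λ★ = 1 is pure diversification with the closed-form uniform solution.  The
target skew normal is set by moment-matching the realized (mean, variance,
skewness) of a reference portfolio (the λ = 1 mean-variance optimum in the
worked pipeline), or supplied directly.  Frontier summaries report realized
moments, normalized entropy, W2² to the target, and the number of weights
below 1e-6 ("zero weights"; the threshold is a package convention).  Monthly
aggregation of higher-frequency tables sums simple returns by default (log
returns behind a flag); the choice is immaterial to the synthetic pipelines.

## Synthetic data

`gen_survey` is described above.  `gen_fairness` draws standard-normal
covariates and y = x'θ_group + shift·1{T} + noise; the default shift of five
noise standard deviations separates the three schemes clearly (the regime in
which ordering tests are powered), and equal coefficients across groups keep
the parity discrepancy a pure location shift, so the unconstrained W2² is
approximately shift².  `gen_returns` uses a Gaussian copula with skew-normal
marginals; defaults emulate monthly equity excess returns (means 0.4–1.1%,
standard deviations 5–10%, mild negative skew, cross-correlation 0.35).
What the generators deliberately do not emulate: real survey strata/clusters
and nonresponse, non-Gaussian covariates or heteroscedastic noise in the
fairness cohorts, and volatility clustering or fat-tailed copulas in
returns.  Tests passing on these generators therefore validate the
estimators and solvers under their stated models, not robustness to real
data pathologies.

## Problem sizes

The bundled study harness runs 100 replicates per cell with populations of
100,000; the bootstrap estimator runs at M = 20 pseudo-populations of size
10,000.  These sizes keep a full grid cell in the minutes range on one core
while leaving Monte-Carlo error (binomial sd ≈ 0.02–0.05 on coverages,
~5–10% on biases) small relative to the effects studied; both are exposed as
parameters.

## Known limitations

* All W2 computations are one-dimensional; multivariate couplings and
  entropic/Sinkhorn transport are out of scope.
* The constrained solver's bisection assumes W2²(λ) is monotone along the
  penalized path, which holds for the concave objective but is resolved only
  to the stated tolerances.
* The BDCM profile relies on a flat-region convention (initialization at the
  pseudo-sample ML fit) when both constraints are slack; alternative
  conventions move σ̂² within the feasible band.
* The guided portfolio objective is nonconvex; multi-start local search
  reports the best local optimum found, and the d ≤ 3 grid fallback used in
  validation is the only global guarantee.
* Under strongly informative probit selection the inverse-probability
  weights have effectively unbounded second moments; all weighted estimators
  (PMLE, BDCM) are then noisy and their intervals undercover, as discussed
  above.
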