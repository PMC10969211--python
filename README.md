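# otmaxent

Distribution-guided maximum-entropy reweighting of empirical data via optimal
transport, with three bundled pipelines: semi-parametric inference for complex
surveys, demographic parity in regression, and entropy-based portfolio
allocation.

## The problem

Many statistical tasks call for an optimally *reweighted* version of the
empirical distribution of observed data: survey samples must be adjusted for
unequal inclusion probabilities, regression fits must be adjusted so a
protected group's fitted-value distribution matches a reference group's, and
portfolio weights must be steered toward a posited return distribution
without abandoning diversification.  Classical empirical-likelihood methods
constrain the reweighting through moment conditions Σᵢ wᵢ g(sᵢ, θ) = 0, but
many natural constraints — "stay close to a skew-normal law" — have no
convenient moment form.

`otmaxent` implements the nonparametric middle ground: choose the
maximum-entropy weights on the observed atoms subject to a proximity
constraint in the squared 2-Wasserstein metric to a parametric target f_θ,

    w★ = argmax_{w ∈ S_{n−1}}  Hₙ(w)    s.t.   W2²( Σᵢ wᵢ δ_{sᵢ}, f_θ ) ≤ ε,

or its penalized form max_w Hₙ(w) − λ·W2².  In one dimension
W2²(p, q) = ∫₀¹ (F_p⁻¹(u) − F_q⁻¹(u))² du, which the package evaluates
segment-exactly for weighted samples against normal, skew-normal, and
discrete targets — including the gradients that make the simplex solvers and
the downstream pipelines fast.  See `docs/methods.md` for the full model,
solver, and design documentation.

## Worked example

Reweight a right-skewed sample toward a normal model, halving its transport
distance while barely spending entropy:

```python
import numpy as np
from otmaxent import (WeightedSample, TargetDistribution,
                      maxent_constrained, w2sq_to_target)

rng = np.random.default_rng(42)
x = rng.gamma(shape=2.0, scale=1.0, size=200)   # right-skewed sample
target = TargetDistribution.normal(2.0, 2.0)    # posited model

d0 = w2sq_to_target(WeightedSample.uniform(x), target, method="exact")
res = maxent_constrained(x, target, eps=0.5 * d0)
print(f"uniform-weight W2^2 to N(2, 2): {d0:.4f}")
print(f"constrained solve: W2^2 = {res.w2sq:.4f} (eps = {0.5*d0:.4f})")
print(f"entropy: {res.entropy:.4f} of max {np.log(200):.4f}; lam = {res.lam:.3f}")
```

prints

```
uniform-weight W2^2 to N(2, 2): 0.2590
constrained solve: W2^2 = 0.1295 (eps = 0.1295)
entropy: 5.2841 of max 5.2983; lam = 0.428
```

The uniform weights sit at W2² ≈ 0.259 from the target; the constrained
solve reaches the requested ε exactly (the constraint is active, with
equivalent penalty λ ≈ 0.43) while the weight entropy drops only from 5.298
(uniform, log 200) to 5.284 — a nearly uniform reweighting that is twice as
close to the model.

The pipelines are available both as library functions
(`pmle_fit`, `bdcm_fit`, `fit_in_model`, `fit_two_step`,
`ot_maxent_portfolio`, …) and through a CLI:

```bash
otmaxent simulate survey --seed 3 --n 500 --out sim/
otmaxent survey-fit --input sim/survey.csv --estimator BDCM --out fit/
otmaxent fair-fit --input cohort.csv --lambda-star 0.0 --out fair/
otmaxent portfolio --input returns.csv --monthly-aggregate simple --out pf/
```

Every output directory contains a JSON manifest (command, options, seed,
version) sufficient to re-run the command bit-identically.

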