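"""Portfolio allocation: mean-variance, moment-constrained max-entropy, and
the skew-normal-guided optimal-transport/entropy objective.

Given excess returns R (n periods x d assets) with sample moments
mu = (1/n) sum_i R(i) and Sigma = (1/n) sum_i (R(i)-mu)(R(i)-mu)', three
allocators over the simplex {w >= 0, sum w = 1} are provided:

* Markowitz mean-variance:  argmax_w  w'mu - (lam/2) w'Sigma w;
* moment-constrained maximum entropy:  argmax_w H_d(w)  subject to
  w'mu >= mu0 and w'Sigma w <= sigma0^2 (diversification shrinkage under
  moment targets);
* the distribution-guided allocator

      argmin_w (1 - lam*) W2^2( (1/n) sum_i delta_{w'R(i)}, f_theta0 )
               - lam* b_d H_d(w),       b_d = 1 / log d,

  which steers the *empirical law of the realized portfolio return* toward a
  target skew-normal f_theta0 while b_d H_d(w) in [0, 1] rewards diversity.
  Unlike the core reweighting problem, the atoms w'R(i) move with w (weights
  stay uniform at 1/n), which makes the objective nonconvex and only
  piecewise smooth (through the sort of the portfolio returns); it is solved
  by multi-start SLSQP with fixed-seed Dirichlet starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import InfeasibleConstraintError
from .distributions import SkewNormalParams, TargetDistribution

__all__ = [
    "PortfolioSummary",
    "mv_weights",
    "maxent_moment_portfolio",
    "ot_maxent_portfolio",
    "portfolio_frontier",
]

_ZERO_WEIGHT_TOL = 1e-6


@dataclass(frozen=True)
class PortfolioSummary:
    """Realized-return moments and diversity diagnostics of an allocation."""

    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float
    entropy_normalized: float
    w2sq: float
    n_zero_weights: int
    lambda_star: float = float("nan")


def _check_returns(returns: np.ndarray) -> np.ndarray:
    r = np.atleast_2d(np.asarray(returns, dtype=float))
    if r.shape[0] < 2 or r.shape[1] < 1:
        raise ValueError("returns must be an (n >= 2) x (d >= 1) matrix")
    if not np.all(np.isfinite(r)):
        raise ValueError("returns must be finite")
    return r


def sample_moments(returns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Population-style (divide by n) mean vector and covariance matrix."""
    r = _check_returns(returns)
    mu = r.mean(axis=0)
    c = r - mu
    return mu, c.T @ c / r.shape[0]


def _simplex_slsqp(objective, jac, d, starts, constraints=()):
    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(d)}]
    cons.extend(constraints)
    best = None
    for w0 in starts:
        res = optimize.minimize(
            objective,
            w0,
            jac=jac,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * d,
            constraints=cons,
            options={"maxiter": 400, "ftol": 1e-12},
        )
        w = np.clip(res.x, 0.0, None)
        w /= w.sum()
        val = objective(w)
        if best is None or val < best[1]:
            best = (w, val)
    return best[0]


def mv_weights(returns, risk_aversion: float) -> np.ndarray:
    """Markowitz mean-variance weights on the simplex (long-only)."""
    if risk_aversion <= 0.0:
        raise ValueError("risk aversion must be strictly positive")
    r = _check_returns(returns)
    d = r.shape[1]
    if d == 1:
        return np.ones(1)
    mu, sigma = sample_moments(r)
    if np.min(np.linalg.eigvalsh(sigma)) < 1e-12:
        import warnings

        warnings.warn("near-singular covariance: adding 1e-10 ridge")
        sigma = sigma + 1e-10 * np.eye(d)

    def obj(w):
        return -(w @ mu) + 0.5 * risk_aversion * w @ sigma @ w

    def jac(w):
        return -mu + risk_aversion * sigma @ w

    return _simplex_slsqp(obj, jac, d, [np.full(d, 1.0 / d)])


def maxent_moment_portfolio(returns, mu0: float, sigma0sq: float) -> np.ndarray:
    """Maximum-entropy weights under mean >= mu0 and variance <= sigma0^2."""
    r = _check_returns(returns)
    d = r.shape[1]
    mu, sigma = sample_moments(r)
    if d == 1:
        w = np.ones(1)
        if mu[0] < mu0 - 1e-12 or sigma[0, 0] > sigma0sq + 1e-12:
            raise InfeasibleConstraintError("single-asset constraints violated")
        return w
    # feasibility: maximize attainable mean subject to the variance cap
    mean_cap = _simplex_slsqp(
        lambda w: -(w @ mu),
        lambda w: -mu,
        d,
        [np.full(d, 1.0 / d)],
        constraints=[
            {
                "type": "ineq",
                "fun": lambda w: sigma0sq - w @ sigma @ w,
                "jac": lambda w: -2.0 * sigma @ w,
            }
        ],
    )
    if mean_cap @ sigma @ mean_cap > sigma0sq + 1e-8:
        raise InfeasibleConstraintError(
            f"variance cap {sigma0sq:.6g} below the minimum achievable "
            f"portfolio variance"
        )
    if mean_cap @ mu < mu0 - 1e-9:
        raise InfeasibleConstraintError(
            f"mean target {mu0:.6g} outside the feasible range "
            f"(max achievable under the variance cap: {mean_cap @ mu:.6g})"
        )

    def obj(w):
        wc = np.clip(w, 1e-12, None)
        return float((wc * np.log(wc)).sum())

    def jac(w):
        return np.log(np.clip(w, 1e-12, None)) + 1.0

    cons = [
        {"type": "ineq", "fun": lambda w: w @ mu - mu0, "jac": lambda w: mu},
        {
            "type": "ineq",
            "fun": lambda w: sigma0sq - w @ sigma @ w,
            "jac": lambda w: -2.0 * sigma @ w,
        },
    ]
    return _simplex_slsqp(obj, jac, d, [np.full(d, 1.0 / d), mean_cap], constraints=cons)


def _ot_objective_factory(r: np.ndarray, target: TargetDistribution, lambda_star: float):
    n, d = r.shape
    b_d = 1.0 / math.log(d) if d > 1 else 1.0
    # int of F^{-1} over each uniform segment [i/n, (i+1)/n]: fixed per target
    edges = np.arange(n + 1) / n
    g1 = target.quantile_integral(edges)
    dg1 = np.diff(g1)
    ex2 = target.second_moment()

    def value_and_grad(w):
        s = r @ w
        order = np.argsort(s, kind="stable")
        ss = s[order]
        w2 = float(np.sum(ss**2) / n - 2.0 * np.sum(ss * dg1) + ex2)
        gs = 2.0 * (ss / n - dg1)  # d w2 / d s_(i)
        grad_w2 = r[order].T @ gs
        wc = np.clip(w, 1e-12, None)
        h = float(-(wc * np.log(wc)).sum())
        grad_h = -(np.log(wc) + 1.0)
        val = (1.0 - lambda_star) * w2 - lambda_star * b_d * h
        grad = (1.0 - lambda_star) * grad_w2 - lambda_star * b_d * grad_h
        return val, grad, w2, h

    return value_and_grad, b_d


def summarize(returns, w, target: TargetDistribution, lambda_star: float = float("nan")) -> PortfolioSummary:
    """Moments of the realized portfolio returns plus diversity diagnostics."""
    r = _check_returns(returns)
    w = np.asarray(w, dtype=float)
    s = r @ w
    m = s.mean()
    c = s - m
    m2 = float((c**2).mean())
    m3 = float((c**3).mean())
    m4 = float((c**4).mean())
    d = r.shape[1]
    b_d = 1.0 / math.log(d) if d > 1 else 1.0
    vg, _ = _ot_objective_factory(r, target, 0.0)
    _, _, w2, h = vg(w)
    return PortfolioSummary(
        mean=float(m),
        variance=m2,
        skewness=m3 / m2**1.5 if m2 > 0 else 0.0,
        excess_kurtosis=m4 / m2**2 - 3.0 if m2 > 0 else 0.0,
        entropy_normalized=min(b_d * h, 1.0) if d > 1 else 0.0,
        w2sq=w2,
        n_zero_weights=int(np.sum(w < _ZERO_WEIGHT_TOL)),
        lambda_star=lambda_star,
    )


def ot_maxent_portfolio(
    returns,
    target: SkewNormalParams | TargetDistribution,
    lambda_star: float,
    n_starts: int = 10,
    seed: int = 20240311,
) -> tuple[np.ndarray, PortfolioSummary]:
    """Skew-normal-guided max-entropy allocation (multi-start local search).

    Minimizes (1 - lam*) W2^2(empirical law of w'R, target) - lam* b_d H_d(w)
    over the simplex.  lambda_star = 1 reduces to pure entropy, whose optimum
    is uniform and is returned in closed form.
    """
    if not 0.0 <= lambda_star <= 1.0:
        raise ValueError("lambda_star must lie in [0, 1]")
    r = _check_returns(returns)
    n, d = r.shape
    if isinstance(target, SkewNormalParams):
        target = TargetDistribution.from_params(target)
    if d == 1 or lambda_star == 1.0:
        w = np.full(d, 1.0 / d)
        return w, summarize(r, w, target, lambda_star)
    vg, _ = _ot_objective_factory(r, target, lambda_star)

    rng = np.random.default_rng(seed)
    starts = [np.full(d, 1.0 / d)] + [rng.dirichlet(np.ones(d)) for _ in range(n_starts)]
    w = _simplex_slsqp(lambda w: vg(w)[0], lambda w: vg(w)[1], d, starts)
    return w, summarize(r, w, target, lambda_star)


def portfolio_frontier(returns, target, lambda_grid, n_starts: int = 10, seed: int = 20240311):
    """Run the guided allocator over a lambda* grid; one summary row each."""
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    rows = []
    for lam in lambda_grid:
        _, summary = ot_maxent_portfolio(returns, target, float(lam), n_starts=n_starts, seed=seed)
        rows.append(summary)
    return rows
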