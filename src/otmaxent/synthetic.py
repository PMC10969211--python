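"""Seeded generators for the three input kinds the pipelines consume.

* informative-selection survey samples from a bivariate-normal finite
  population with probit inclusion probabilities,
* two-group regression cohorts with a group shift in the response
  (the structure of fairness benchmarks with discrepant outcome
  distributions), and
* skewed, cross-correlated asset-return matrices (Gaussian copula with
  skew-normal marginals).

All generators are pure functions of (config, seed): the same inputs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .distributions import MomentTargets, SkewNormalParams, TargetDistribution, match_skew_normal_moments

__all__ = [
    "SurveySimConfig",
    "FairSimConfig",
    "ReturnsSimConfig",
    "gen_survey",
    "gen_fairness",
    "gen_returns",
]


@dataclass(frozen=True)
class SurveySimConfig:
    """Bivariate-normal finite population with probit selection on Z.

    (X, Z) are jointly normal with mean (mu_x, mu_z), marginal variances
    (var_x, var_z) and correlation rho.  The inclusion probability of a unit
    is pi* = Phi(beta0 + beta1 * z) with z the standardized selection
    variable (Z - mu_z) / sd_z; the analyst observes only the sampled X
    values and survey weights proportional to 1 / pi*, rescaled to sum n.
    """

    n_pop: int = 100_000
    n: int = 500
    rho: float = 0.8
    mu: tuple[float, float] = (0.0, 10.0)
    variances: tuple[float, float] = (4.0, 16.0)
    beta0: float = 0.1
    beta1: float = -1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_pop >= self.n >= 2):
            raise ValueError("need n_pop >= n >= 2")
        if not abs(self.rho) < 1.0:
            raise ValueError("|rho| must be < 1")
        if min(self.variances) <= 0.0:
            raise ValueError("variances must be positive")


def gen_survey(config: SurveySimConfig, rng: np.random.Generator | None = None):
    """Draw a finite population and an informative survey sample from it.

    Returns ``(population, data)`` where ``population`` is the (N, 2) array of
    (X, Z) values and ``data`` is a :class:`~otmaxent.survey.SurveyData` with
    the sampled X and weights proportional to inverse inclusion probability
    (normalized to sum 1, then rescaled to sum n).  Z is never exposed to the
    estimators.

    Selection is probability-proportional-to-pi* without replacement via an
    exponential race (unit i is kept if E_i / pi*_i is among the n smallest,
    E_i iid exponential), computed on the log scale so that arbitrarily small
    inclusion probabilities are handled exactly.
    """
    from .survey import SurveyData

    rng = np.random.default_rng(config.seed) if rng is None else rng
    mx, mz = config.mu
    vx, vz = config.variances
    sx, sz = math.sqrt(vx), math.sqrt(vz)
    z_std = rng.standard_normal(config.n_pop)
    x = mx + sx * (
        config.rho * z_std + math.sqrt(1.0 - config.rho**2) * rng.standard_normal(config.n_pop)
    )
    z = mz + sz * z_std
    population = np.column_stack([x, z])

    log_pstar = special.log_ndtr(config.beta0 + config.beta1 * z_std)
    keys = np.log(rng.exponential(size=config.n_pop)) - log_pstar
    sel = np.argpartition(keys, config.n)[: config.n]
    sel = sel[np.argsort(keys[sel])]
    log_w = -log_pstar[sel]
    w = np.exp(log_w - log_w.max())
    pi = w / w.sum() * config.n
    return population, SurveyData(x=x[sel], pi=pi)


@dataclass(frozen=True)
class FairSimConfig:
    """Two-group linear-regression cohort with a response shift in group T.

    y = x' coef_group + shift * 1{group == T} + noise.  The default shift of
    five noise standard deviations produces clearly discrepant fitted-value
    distributions between groups, the regime in which the fairness schemes
    separate.
    """

    n_s: int = 150
    n_t: int = 150
    p: int = 3
    coef_s: tuple[float, ...] = (1.0, -0.5, 0.25)
    coef_t: tuple[float, ...] = (1.0, -0.5, 0.25)
    shift: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_s, self.n_t) < 2:
            raise ValueError("both groups need at least 2 observations")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")
        if len(self.coef_s) != self.p or len(self.coef_t) != self.p:
            raise ValueError("coefficient vectors must have length p")


def gen_fairness(config: FairSimConfig, rng: np.random.Generator | None = None):
    """Gaussian covariates; group-specific linear signal; labeled groups."""
    from .fairness import FairnessData

    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_s + config.n_t
    x = rng.standard_normal((n, config.p))
    coef = np.vstack([config.coef_s, config.coef_t])
    group = np.array([0] * config.n_s + [1] * config.n_t)
    y = (
        np.einsum("ij,ij->i", x, coef[group])
        + config.shift * group
        + config.noise_sd * rng.standard_normal(n)
    )
    labels = np.where(group == 0, "S", "T")
    return FairnessData(x=x, y=y, a=labels)


def _default_marginals() -> tuple[SkewNormalParams, ...]:
    # monthly excess-return-like marginals: small positive mean, 6-10% sd,
    # mild negative skew
    specs = [
        (0.006, 0.0036, -0.30),
        (0.009, 0.0064, -0.20),
        (0.004, 0.0025, -0.35),
        (0.007, 0.0049, -0.25),
        (0.011, 0.0100, -0.15),
    ]
    return tuple(match_skew_normal_moments(MomentTargets(*s)) for s in specs)


@dataclass(frozen=True)
class ReturnsSimConfig:
    """Gaussian copula over assets with skew-normal marginal returns."""

    n: int = 240
    d: int = 5
    marginals: tuple[SkewNormalParams, ...] = field(default_factory=_default_marginals)
    correlation: float | np.ndarray = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1:
            raise ValueError("need n >= 2 periods and d >= 1 assets")
        if len(self.marginals) < self.d:
            raise ValueError("need one marginal per asset")

    def correlation_matrix(self) -> np.ndarray:
        if np.isscalar(self.correlation):
            c = np.full((self.d, self.d), float(self.correlation))
            np.fill_diagonal(c, 1.0)
        else:
            c = np.asarray(self.correlation, dtype=float)
        if c.shape != (self.d, self.d):
            raise ValueError("correlation matrix has wrong shape")
        if np.min(np.linalg.eigvalsh(c)) <= 1e-12:
            raise ValueError("correlation matrix must be positive definite")
        return c


def gen_returns(config: ReturnsSimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate an (n, d) excess-return matrix (rows = periods)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chol = np.linalg.cholesky(config.correlation_matrix())
    g = rng.standard_normal((config.n, config.d)) @ chol.T
    u = np.clip(special.ndtr(g), 1e-12, 1.0 - 1e-12)
    out = np.empty_like(u)
    for j in range(config.d):
        t = TargetDistribution.from_params(config.marginals[j])
        out[:, j] = t.ppf(u[:, j])
    return out
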