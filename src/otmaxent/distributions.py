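"""Parametric one-dimensional target laws.

The reweighting machinery measures the 2-Wasserstein distance between a
weighted empirical distribution and a continuous "guiding" law.  Two families
are supported: the normal distribution and the skew normal SN(zeta, omega,
alpha) with density

    f(z) = (2 / omega) * phi((z - zeta) / omega) * Phi(alpha * (z - zeta) / omega),

where phi and Phi are the standard normal pdf and cdf.  alpha = 0 recovers the
normal law; alpha > 0 produces positive (right) skewness.  Writing
delta = alpha / sqrt(1 + alpha^2), the first three moments are

    mean      = zeta + omega * delta * sqrt(2 / pi)
    variance  = omega^2 * (1 - 2 * delta^2 / pi)
    skewness  = ((4 - pi) / 2) * (delta * sqrt(2/pi))^3 / (1 - 2 delta^2 / pi)^(3/2)

The skewness is bounded: |skewness| < 0.9952717 (the delta -> 1 limit), so not
every moment triple can be met by a skew normal.

Besides the usual pdf/cdf/quantile surface, :class:`TargetDistribution`
exposes the partial expectation E[X; X <= q] and the quantile integral
G1(c) = int_0^c F^{-1}(u) du.  These are the only ingredients needed for the
segment-exact evaluation (and gradient) of the 1-D squared 2-Wasserstein
distance between a weighted discrete sample and the target, so they are
implemented in closed form for both families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SkewNormalParams",
    "MomentTargets",
    "TargetDistribution",
    "UnattainableSkewnessError",
    "MAX_ABS_SKEWNESS",
    "skew_normal_pdf",
    "skew_normal_cdf",
    "skew_normal_quantile",
    "skew_normal_moments",
    "match_skew_normal_moments",
]

_SQRT_2_PI = math.sqrt(2.0 / math.pi)


def _skewness_from_delta(delta: float) -> float:
    m = delta * _SQRT_2_PI
    v = 1.0 - 2.0 * delta * delta / math.pi
    return (4.0 - math.pi) / 2.0 * m**3 / v**1.5


#: Supremum of |skewness| over the skew-normal family (the |alpha| -> inf limit).
MAX_ABS_SKEWNESS = _skewness_from_delta(1.0)


class UnattainableSkewnessError(ValueError):
    """Requested skewness exceeds the skew-normal bound of ~0.9953."""


@dataclass(frozen=True)
class SkewNormalParams:
    """Location / scale / slant parameters of a skew normal law."""

    location: float
    scale: float
    slant: float

    def __post_init__(self) -> None:
        if not (self.scale > 0.0 and np.isfinite(self.scale)):
            raise ValueError(f"scale must be strictly positive, got {self.scale}")
        if not (np.isfinite(self.location) and np.isfinite(self.slant)):
            raise ValueError("location and slant must be finite")

    @property
    def delta(self) -> float:
        a = self.slant
        return a / math.sqrt(1.0 + a * a)


@dataclass(frozen=True)
class MomentTargets:
    """Target (mean, variance, skewness) for a portfolio return law."""

    mean: float
    variance: float
    skewness: float

    def __post_init__(self) -> None:
        if not (self.variance > 0.0):
            raise ValueError("variance must be strictly positive")
        if abs(self.skewness) >= MAX_ABS_SKEWNESS:
            raise UnattainableSkewnessError(
                f"|skewness| = {abs(self.skewness):.6f} is not attainable by a "
                f"skew normal law (bound {MAX_ABS_SKEWNESS:.7f})"
            )


def skew_normal_pdf(z, params: SkewNormalParams):
    return stats.skewnorm.pdf(z, params.slant, loc=params.location, scale=params.scale)


def skew_normal_cdf(z, params: SkewNormalParams):
    return stats.skewnorm.cdf(z, params.slant, loc=params.location, scale=params.scale)


def skew_normal_quantile(u, params: SkewNormalParams):
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("quantile level must lie strictly inside (0, 1)")
    q = stats.skewnorm.ppf(u, params.slant, loc=params.location, scale=params.scale)
    # polish scipy's inversion with Newton steps on the cdf (the far tail of a
    # strongly slanted law is otherwise only ~1e-7 accurate)
    for _ in range(3):
        f = stats.skewnorm.pdf(q, params.slant, loc=params.location, scale=params.scale)
        err = stats.skewnorm.cdf(q, params.slant, loc=params.location, scale=params.scale) - u
        step = np.where(f > 0.0, err / np.where(f > 0.0, f, 1.0), 0.0)
        q = q - np.clip(step, -1.0, 1.0)
    return float(q) if q.ndim == 0 else q


def skew_normal_moments(params: SkewNormalParams) -> tuple[float, float, float]:
    """(mean, variance, skewness) implied by (zeta, omega, alpha)."""
    d = params.delta
    mean = params.location + params.scale * d * _SQRT_2_PI
    var = params.scale**2 * (1.0 - 2.0 * d * d / math.pi)
    return mean, var, _skewness_from_delta(d)


def match_skew_normal_moments(targets: MomentTargets) -> SkewNormalParams:
    """Invert the moment map: find (zeta, omega, alpha) with the given
    mean, variance and skewness.

    The skewness depends on delta = alpha / sqrt(1 + alpha^2) alone and is
    strictly increasing in delta, so delta is found by bracketed root-finding;
    omega and zeta then follow in closed form.
    """
    g = targets.skewness
    if g == 0.0:
        delta = 0.0
    else:
        hi = 1.0 - 1e-13
        delta = optimize.brentq(
            lambda d: _skewness_from_delta(d) - g,
            -hi,
            hi,
            xtol=1e-14,
            rtol=8.9e-16,
        )
    alpha = delta / math.sqrt(max(1.0 - delta * delta, 1e-30))
    omega = math.sqrt(targets.variance / (1.0 - 2.0 * delta * delta / math.pi))
    zeta = targets.mean - omega * delta * _SQRT_2_PI
    return SkewNormalParams(location=zeta, scale=omega, slant=alpha)


class TargetDistribution:
    """A guiding 1-D law: normal or skew normal.

    Wraps the corresponding scipy frozen distribution and adds the closed-form
    partial expectation / quantile integral used by the exact W2 machinery.
    """

    def __init__(self, family: str, **params: float):
        if family == "normal":
            mean = float(params["mean"])
            variance = float(params["variance"])
            if not variance > 0.0:
                raise ValueError("variance must be strictly positive")
            self._mu = mean
            self._sigma = math.sqrt(variance)
            self._dist = stats.norm(loc=self._mu, scale=self._sigma)
        elif family == "skew_normal":
            sn = SkewNormalParams(
                location=float(params["location"]),
                scale=float(params["scale"]),
                slant=float(params["slant"]),
            )
            self._sn = sn
            self._dist = stats.skewnorm(sn.slant, loc=sn.location, scale=sn.scale)
        else:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.params = {k: float(v) for k, v in params.items()}

    # -- constructors -----------------------------------------------------
    @classmethod
    def normal(cls, mean: float, variance: float) -> "TargetDistribution":
        return cls("normal", mean=mean, variance=variance)

    @classmethod
    def skew_normal(cls, location: float, scale: float, slant: float) -> "TargetDistribution":
        return cls("skew_normal", location=location, scale=scale, slant=slant)

    @classmethod
    def from_params(cls, params: SkewNormalParams) -> "TargetDistribution":
        return cls.skew_normal(params.location, params.scale, params.slant)

    @classmethod
    def from_moments(cls, targets: MomentTargets) -> "TargetDistribution":
        return cls.from_params(match_skew_normal_moments(targets))

    # -- distribution surface --------------------------------------------
    def pdf(self, x):
        return self._dist.pdf(x)

    def cdf(self, x):
        return self._dist.cdf(x)

    def ppf(self, u):
        u = np.clip(np.asarray(u, dtype=float), 1e-15, 1.0 - 1e-15)
        return self._dist.ppf(u)

    def mean(self) -> float:
        if self.family == "normal":
            return self._mu
        return skew_normal_moments(self._sn)[0]

    def variance(self) -> float:
        if self.family == "normal":
            return self._sigma**2
        return skew_normal_moments(self._sn)[1]

    def skewness(self) -> float:
        if self.family == "normal":
            return 0.0
        return skew_normal_moments(self._sn)[2]

    def moments(self) -> tuple[float, float, float]:
        return self.mean(), self.variance(), self.skewness()

    def second_moment(self) -> float:
        m = self.mean()
        return self.variance() + m * m

    # -- W2 ingredients ---------------------------------------------------
    def partial_expectation(self, q):
        """E[X; X <= q] = int_{-inf}^{q} x f(x) dx, vectorised in q."""
        q = np.asarray(q, dtype=float)
        if self.family == "normal":
            t = (q - self._mu) / self._sigma
            out = self._mu * stats.norm.cdf(t) - self._sigma * stats.norm.pdf(t)
        else:
            sn = self._sn
            t = (q - sn.location) / sn.scale
            a = sn.slant
            r = math.sqrt(1.0 + a * a)
            # E[U; U <= t] for standard SN(0, 1, alpha)
            eu = -2.0 * stats.norm.pdf(t) * stats.norm.cdf(a * t) + (
                sn.delta * _SQRT_2_PI
            ) * stats.norm.cdf(t * r)
            out = sn.location * self.cdf(q) + sn.scale * eu
        return float(out) if out.ndim == 0 else out

    def quantile_integral(self, c):
        """G1(c) = int_0^c F^{-1}(u) du, vectorised in c in [0, 1]."""
        c = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
        interior = np.clip(c, 1e-15, 1.0 - 1e-15)
        out = self.partial_expectation(self._dist.ppf(interior))
        out = np.where(c <= 0.0, 0.0, out)
        out = np.where(c >= 1.0, self.mean(), out)
        return float(out) if out.ndim == 0 else out
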