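"""Demographic parity in the Wasserstein metric for regression.

A predictor h achieves demographic parity (in the W2 sense, with bias eps)
when the distribution of fitted values in the protected group T, after
reweighting, is within eps of the fitted-value distribution in group S:
W2^2(F_h^S, F_h^T) <= eps, where F_h^S is the uniform ECDF of group-S fitted
values and F_h^T = sum_i w_i delta_{h(x_i^T)} is a weighted ECDF over group T.

Two estimation schemes are provided, both governed by a balance parameter
lambda_star in [0, 1] that trades parity (lambda_star -> 0) against minimal
reweighting, i.e. maximal entropy of w (lambda_star -> 1):

* the joint "in-model" scheme maximizes

    - (1/n_S) sum_S l_i(theta_S) - sum_T w_i l_i(theta_T)
    - (1 - lambda_star) W2^2(F_h^S, F_h^T) - lambda_star sum_T w_i log w_i

  over (theta_S, theta_T, sigma^2, w), with squared-error losses
  l_i = (y_i - x_i' theta)^2 / (2 sigma^2), by block-coordinate ascent;

* the "two-step" scheme first fits the two groups by ordinary least squares
  and then solves the weights-only subproblem at the fixed fits.

Fair predictions for new group-T points use a Nadaraya-Watson estimate whose
kernel weights are multiplied by the parity weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import WeightedSample, _check_simplex, _DiscreteTarget, _solve_simplex, entropy, w2sq_discrete

__all__ = ["FairnessData", "FairFit", "parity_w2sq", "fit_in_model", "fit_two_step", "fair_predict"]


@dataclass(frozen=True)
class FairnessData:
    """Covariates, continuous response, and a binary protected attribute."""

    x: np.ndarray
    y: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        y = np.asarray(self.y, dtype=float)
        a = np.asarray(self.a)
        if x.shape[0] != y.size or a.size != y.size:
            raise ValueError("x, y and a must agree in length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("missing or non-finite values are not supported")
        labels = np.unique(a)
        if labels.size != 2:
            raise ValueError(f"protected attribute must be binary, got labels {labels!r}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "a", a)

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        labels = sorted(np.unique(self.a).tolist())
        s_label = "S" if "S" in labels else labels[0]
        t_label = "T" if "T" in labels else [l for l in labels if l != s_label][0]
        return self.a == s_label, self.a == t_label

    @property
    def n_s(self) -> int:
        return int(self.masks()[0].sum())

    @property
    def n_t(self) -> int:
        return int(self.masks()[1].sum())


@dataclass
class FairFit:
    """Fitted parity model: group coefficients, noise scale, T weights."""

    theta_s: np.ndarray
    theta_t: np.ndarray
    sigma2: float
    weights_t: np.ndarray
    lambda_star: float
    parity_w2sq: float
    objective_path: np.ndarray | None = None
    data: FairnessData | None = None


def parity_w2sq(fit_values_s, fit_values_t, weights_t) -> float:
    """W2^2 between the uniform S fitted-value ECDF and the weighted T ECDF."""
    fit_values_s = np.asarray(fit_values_s, dtype=float)
    fit_values_t = np.asarray(fit_values_t, dtype=float)
    if fit_values_s.size == 0 or fit_values_t.size == 0:
        raise ValueError("fitted-value vectors must be non-empty")
    p = WeightedSample.uniform(fit_values_s)
    q = WeightedSample(fit_values_t, _check_simplex(weights_t))
    return w2sq_discrete(p, q)


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x])


def _ols(x, y, w=None) -> np.ndarray:
    d = _design(x)
    if w is not None:
        sw = np.sqrt(w)
        d = d * sw[:, None]
        y = y * sw
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        raise ValueError(
            "rank-deficient design: collinear columns "
            f"{[j for j in range(d.shape[1]) if np.allclose(np.linalg.lstsq(np.delete(d, j, axis=1), d[:, j], rcond=None)[1], 0)]}"
        )
    beta, *_ = np.linalg.lstsq(d, y, rcond=None)
    return beta


def _w2sq_grad_atoms(values_a, weights_a, target_b: _DiscreteTarget):
    """W2^2 between (values_a, weights_a) and a fixed discrete target, plus
    its gradient with respect to the atoms values_a.

    From the segment form W2^2 = sum_k a_(k)^2 dc_k - 2 a_(k) dG1_k + E_b[X^2],
    the atom gradient is d W2^2 / d a_(k) = 2 (a_(k) dc_k - dG1_k).
    """
    order = np.argsort(values_a, kind="stable")
    a = values_a[order]
    c = np.cumsum(weights_a[order])
    c[-1] = 1.0
    g1 = target_b.quantile_integral(c)
    dg1 = np.diff(np.concatenate(([0.0], g1)))
    dc = np.diff(np.concatenate(([0.0], c)))
    w2 = float(np.sum(a**2 * dc - 2.0 * a * dg1) + target_b.second_moment())
    grad_sorted = 2.0 * (a * dc - dg1)
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return w2, grad


def _weight_subproblem(h_t, target_s, lambda_star, linear=None, w0=None, fast=False):
    """max_w  lambda* H(w) - (1 - lambda*) W2^2 + linear . w  over the simplex.

    ``fast=True`` (used inside block-coordinate sweeps, where the subproblem
    is warm-started and re-solved every sweep) skips the multi-start fallback
    and caps the iteration budget.
    """
    if lambda_star == 1.0 and linear is None:
        n_t = h_t.size
        w = np.full(n_t, 1.0 / n_t)
        return w
    w, *_ = _solve_simplex(
        np.asarray(h_t, dtype=float),
        target_s,
        ent_coef=lambda_star,
        w2_coef=1.0 - lambda_star,
        linear=linear,
        w0=w0,
        tol=1e-9,
        max_iter=600 if fast else 4000,
        n_restarts=0 if fast else 5,
    )
    return w


def fit_two_step(data: FairnessData, lambda_star: float) -> FairFit:
    """Per-group OLS, pooled sigma^2, then the weights-only parity solve."""
    if not 0.0 <= lambda_star <= 1.0:
        raise ValueError("lambda_star must lie in [0, 1]")
    ms, mt = data.masks()
    xs, ys = data.x[ms], data.y[ms]
    xt, yt = data.x[mt], data.y[mt]
    theta_s = _ols(xs, ys)
    theta_t = _ols(xt, yt)
    rs = ys - _design(xs) @ theta_s
    rt = yt - _design(xt) @ theta_t
    sigma2 = float((rs @ rs + rt @ rt) / (ys.size + yt.size))
    h_s = _design(xs) @ theta_s
    h_t = _design(xt) @ theta_t
    target = _DiscreteTarget(h_s, np.full(h_s.size, 1.0 / h_s.size))
    w = _weight_subproblem(h_t, target, lambda_star)
    return FairFit(
        theta_s=theta_s,
        theta_t=theta_t,
        sigma2=sigma2,
        weights_t=w,
        lambda_star=lambda_star,
        parity_w2sq=parity_w2sq(h_s, h_t, w),
        data=data,
    )


def fit_in_model(
    data: FairnessData,
    lambda_star: float,
    max_sweeps: int = 500,
    tol: float = 1e-8,
) -> FairFit:
    """Joint scheme: block-coordinate ascent on the in-model objective.

    Blocks: (i) theta_S by OLS on S, (ii) theta_T by weighted least squares,
    (iii) sigma^2 profiled as the pooled weighted mean squared residual,
    (iv) weights by the concave simplex subproblem.  Each theta/sigma^2
    block is backtracked toward its candidate so the full objective never
    decreases (the parity term depends on the fits, so a raw least-squares
    step could otherwise overshoot).  Initialized at the two-step fit.
    """
    if not 0.0 <= lambda_star <= 1.0:
        raise ValueError("lambda_star must lie in [0, 1]")
    ms, mt = data.masks()
    xs, ys = data.x[ms], data.y[ms]
    xt, yt = data.x[mt], data.y[mt]
    ds, dt = _design(xs), _design(xt)
    n_s, n_t = ys.size, yt.size

    start = fit_two_step(data, lambda_star)
    theta_s, theta_t = start.theta_s.copy(), start.theta_t.copy()
    sigma2, w = start.sigma2, start.weights_t.copy()

    def objective(th_s, th_t, s2, wv):
        h_s = ds @ th_s
        h_t = dt @ th_t
        rs = ys - h_s
        rt = yt - h_t
        loss = (rs @ rs) / n_s / (2.0 * s2) + float(wv @ rt**2) / (2.0 * s2)
        pw2 = parity_w2sq(h_s, h_t, wv)
        ent = entropy(wv)
        return -loss - (1.0 - lambda_star) * pw2 + lambda_star * ent, pw2

    obj, _ = objective(theta_s, theta_t, sigma2, w)
    path = [obj]

    def backtrack(candidate, current, assemble):
        # move from `current` toward `candidate`, halving the step until the
        # full objective does not decrease
        nonlocal obj
        t = 1.0
        for _ in range(30):
            trial = current + t * (candidate - current)
            new_obj, _ = objective(*assemble(trial))
            if new_obj >= obj - 1e-12 * max(1.0, abs(obj)):
                obj = new_obj
                return trial
            t *= 0.5
        return current

    def theta_gradient_step(th_s, th_t):
        # ascent direction on the full objective in (theta_S, theta_T): the
        # least-squares blocks ignore the parity term, so a gradient step is
        # what lets the fits themselves move the two ECDFs together
        h_s = ds @ th_s
        h_t = dt @ th_t
        rs = ys - h_s
        rt = yt - h_t
        tgt_t = _DiscreteTarget(h_t, w)
        tgt_s = _DiscreteTarget(h_s, np.full(n_s, 1.0 / n_s))
        _, gs_atoms = _w2sq_grad_atoms(h_s, np.full(n_s, 1.0 / n_s), tgt_t)
        _, gt_atoms = _w2sq_grad_atoms(h_t, w, tgt_s)
        grad_s = ds.T @ (rs / (n_s * sigma2) - (1.0 - lambda_star) * gs_atoms)
        grad_t = dt.T @ (w * rt / sigma2 - (1.0 - lambda_star) * gt_atoms)
        scale = max(1.0, float(np.max(np.abs(np.concatenate([grad_s, grad_t])))))
        return th_s + grad_s / scale, th_t + grad_t / scale

    for sweep in range(max_sweeps):
        obj_prev = obj
        # (i) theta_S
        theta_s = backtrack(_ols(xs, ys), theta_s, lambda c: (c, theta_t, sigma2, w))
        # (ii) theta_T by w-weighted least squares
        cand = _ols(xt, yt, w=np.clip(w, 1e-12, None))
        theta_t = backtrack(cand, theta_t, lambda c: (theta_s, c, sigma2, w))
        # (ii') joint gradient step so the parity term can steer the fits
        cs, ct = theta_gradient_step(theta_s, theta_t)
        pair = backtrack(
            np.concatenate([cs, ct]),
            np.concatenate([theta_s, theta_t]),
            lambda c: (c[: theta_s.size], c[theta_s.size :], sigma2, w),
        )
        theta_s, theta_t = pair[: theta_s.size], pair[theta_s.size :]
        # (iii) sigma^2 profiled as pooled weighted mean squared residual
        rs = ys - ds @ theta_s
        rt = yt - dt @ theta_t
        cand_s2 = float(((rs @ rs) / n_s + w @ rt**2) / 2.0)
        sigma2 = float(backtrack(np.asarray(cand_s2), np.asarray(sigma2), lambda c: (theta_s, theta_t, float(c), w)))
        # (iv) weights: concave simplex subproblem at the current fits
        h_s = ds @ theta_s
        h_t = dt @ theta_t
        target = _DiscreteTarget(h_s, np.full(n_s, 1.0 / n_s))
        linear = -((yt - h_t) ** 2) / (2.0 * sigma2)
        final_sweep = sweep == max_sweeps - 1
        w = _weight_subproblem(
            h_t, target, lambda_star, linear=linear, w0=w, fast=not final_sweep
        )
        obj, pw2 = objective(theta_s, theta_t, sigma2, w)
        path.append(obj)
        if abs(obj - obj_prev) < tol * max(1.0, abs(obj)):
            # polish the weights at full solver settings before stopping
            w = _weight_subproblem(h_t, target, lambda_star, linear=linear, w0=w)
            obj, pw2 = objective(theta_s, theta_t, sigma2, w)
            path.append(obj)
            break

    h_s = ds @ theta_s
    h_t = dt @ theta_t
    return FairFit(
        theta_s=theta_s,
        theta_t=theta_t,
        sigma2=sigma2,
        weights_t=w,
        lambda_star=lambda_star,
        parity_w2sq=parity_w2sq(h_s, h_t, w),
        objective_path=np.asarray(path),
        data=data,
    )


def fair_predict(fit: FairFit, x_new, group: str, bandwidth: float | None = None) -> float:
    """Predict at a new covariate point.

    Group S uses the linear fit x' theta_S.  Group T uses a Nadaraya-Watson
    estimate over the T training points with Gaussian kernel weights
    multiplied by the parity weights (Silverman's rule bandwidth on the T
    covariates by default), so the reweighting learned for parity carries
    into prediction.
    """
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    if fit.data is None:
        raise ValueError("fit does not carry its training data")
    p = fit.data.x.shape[1]
    if x_new.size != p:
        raise ValueError(f"expected a covariate vector of length {p}, got {x_new.size}")
    if group == "S":
        return float(np.concatenate(([1.0], x_new)) @ fit.theta_s)
    if group != "T":
        raise ValueError(f"unknown group label {group!r}")
    ms, mt = fit.data.masks()
    xt, yt = fit.data.x[mt], fit.data.y[mt]
    n_t = yt.size
    if bandwidth is None:
        sd = xt.std(axis=0, ddof=1).mean()
        bandwidth = 1.06 * max(sd, 1e-12) * n_t ** (-1.0 / 5.0)
    d2 = np.sum((xt - x_new) ** 2, axis=1)
    k = np.exp(-0.5 * d2 / bandwidth**2) * fit.weights_t
    s = k.sum()
    if s <= 0.0:
        # degenerate kernel mass: fall back to the nearest point
        return float(yt[np.argmin(d2)])
    return float(k @ yt / s)
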