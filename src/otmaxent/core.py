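"""Entropy, 1-D optimal transport, and constrained max-entropy weight solvers.

The central object is a weighted empirical distribution sum_i w_i delta_{s_i}
with weights w on the probability simplex.  Its Shannon entropy
H_m(w) = -sum_i w_i log w_i (nats) is maximal, log m, at the uniform weights.
The solvers in this module find the maximum-entropy reweighting of a fixed
atom set subject to

* linear moment conditions  sum_i w_i g_i = 0, and/or
* a proximity constraint in the squared 2-Wasserstein distance to a guiding
  law f_theta, either in primal form  W2^2 <= eps  or in the penalized form
  max_w H(w) - lam * W2^2(sum_i w_i delta_{s_i}, f_theta).

In one dimension W2^2(p, q) = int_0^1 (F_p^{-1}(u) - F_q^{-1}(u))^2 du, the
squared L2 distance between quantile functions.  For a discrete p with sorted
atoms x_(k) and cumulative weights c_k this integral splits into segments
[c_{k-1}, c_k] on which F_p^{-1} is constant, giving the closed form

    W2^2 = sum_k x_(k)^2 (c_k - c_{k-1}) - 2 x_(k) (G1(c_k) - G1(c_{k-1})) + E_q[X^2],

with G1(c) = int_0^c F_q^{-1}(u) du.  This expression is smooth in the
cumulative weights, with gradient

    d W2^2 / d c_k = (x_(k) - x_(k+1)) (x_(k) + x_(k+1) - 2 F_q^{-1}(c_k)),

which is what makes a simple first-order simplex method (entropic mirror
ascent with an exponential-tilt projection onto the moment hyperplane)
practical for the penalized problem.  The objective H(w) - lam W2^2(w) is
concave in w (W2^2 is convex in the weight vector), so the solver certifies a
first-order stationarity residual at the solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .distributions import TargetDistribution

__all__ = [
    "InvalidSimplexError",
    "InfeasibleConstraintError",
    "NumericalFailureError",
    "UnsupportedTargetError",
    "WeightedSample",
    "SimplexSolveResult",
    "entropy",
    "w2sq_discrete",
    "w2sq_to_target",
    "maxent_penalized",
    "maxent_constrained",
    "etel_moment",
]

_SIMPLEX_TOL = 1e-10
_FLOOR = 1e-12


class InvalidSimplexError(ValueError):
    """Weights are not a probability vector."""


class InfeasibleConstraintError(ValueError):
    """The constraint set on the simplex is empty."""


class NumericalFailureError(RuntimeError):
    """An inner optimization failed to converge."""


class UnsupportedTargetError(ValueError):
    """The guiding law lacks the moments required by the operation."""


def _check_simplex(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size < 1:
        raise InvalidSimplexError("weights must be a 1-D vector of length >= 1")
    if np.any(w < -_SIMPLEX_TOL):
        raise InvalidSimplexError(f"negative weight: min = {w.min():.3e}")
    s = w.sum()
    if abs(s - 1.0) > 1e-8:
        raise InvalidSimplexError(f"weights sum to {s!r}, not 1")
    return np.clip(w, 0.0, None)


@dataclass(frozen=True)
class WeightedSample:
    """Atoms with simplex weights: the distribution sum_i w_i delta_{atoms_i}."""

    atoms: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=float)
        weights = _check_simplex(self.weights)
        if atoms.ndim != 1 or atoms.size != weights.size:
            raise ValueError("atoms and weights must be 1-D vectors of equal length")
        if not np.all(np.isfinite(atoms)):
            raise ValueError("atoms must be finite")
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def uniform(cls, atoms) -> "WeightedSample":
        atoms = np.asarray(atoms, dtype=float)
        return cls(atoms, np.full(atoms.size, 1.0 / atoms.size))

    def entropy(self) -> float:
        return entropy(self.weights)


@dataclass
class SimplexSolveResult:
    """Solution container for the constrained/penalized max-entropy problems."""

    weights: np.ndarray
    objective: float
    entropy: float
    w2sq: float
    converged: bool
    iterations: int
    lam: float | None = None
    stationarity: float = field(default=float("nan"), repr=False)


def entropy(weights) -> float:
    """Shannon entropy -sum w_i log w_i in nats, with 0 log 0 = 0."""
    w = _check_simplex(weights)
    nz = w[w > 0.0]
    return float(-(nz * np.log(nz)).sum())


# ---------------------------------------------------------------------------
# Discrete-target adapter: lets the W2 machinery treat a fixed weighted sample
# as the guiding law (used by the fairness pipeline).
# ---------------------------------------------------------------------------


class _DiscreteTarget:
    """Quantile function, G1(c) and E[X^2] of a fixed weighted sample."""

    def __init__(self, values, weights):
        values = np.asarray(values, dtype=float)
        weights = _check_simplex(weights)
        order = np.argsort(values, kind="stable")
        self.y = values[order]
        wq = weights[order]
        self.q = np.cumsum(wq)
        self.q[-1] = 1.0
        self._cum_y = np.cumsum(self.y * wq)
        self._ex2 = float(np.dot(wq, self.y**2))

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        idx = np.minimum(np.searchsorted(self.q, u, side="left"), self.y.size - 1)
        out = self.y[idx]
        return float(out) if out.ndim == 0 else out

    def quantile_integral(self, c):
        c = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
        idx = np.minimum(np.searchsorted(self.q, c, side="left"), self.y.size - 1)
        prev_q = np.where(idx > 0, self.q[idx - 1], 0.0)
        prev_cum = np.where(idx > 0, self._cum_y[idx - 1], 0.0)
        out = prev_cum + self.y[idx] * (c - prev_q)
        return float(out) if out.ndim == 0 else out

    def second_moment(self) -> float:
        return self._ex2

    def mean(self) -> float:
        return float(self._cum_y[-1])


# ---------------------------------------------------------------------------
# Squared 2-Wasserstein distances
# ---------------------------------------------------------------------------


def w2sq_discrete(p: WeightedSample, q: WeightedSample) -> float:
    """Exact W2^2 between two weighted discrete 1-D distributions.

    Merges the cumulative-weight breakpoints of both samples and sums
    (delta cumulative) * (x - y)^2 over the resulting segments, on which both
    quantile functions are constant.
    """
    xs, xc = _sorted_cumulative(p)
    ys, yc = _sorted_cumulative(q)
    grid = np.union1d(xc, yc)
    grid = grid[(grid > 0.0) & (grid <= 1.0)]
    left = np.concatenate(([0.0], grid[:-1]))
    seg = grid - left
    ix = np.minimum(np.searchsorted(xc, left, side="right"), xs.size - 1)
    iy = np.minimum(np.searchsorted(yc, left, side="right"), ys.size - 1)
    return float(np.sum(seg * (xs[ix] - ys[iy]) ** 2))


def _sorted_cumulative(p: WeightedSample) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(p.atoms, kind="stable")
    xs = p.atoms[order]
    c = np.cumsum(p.weights[order])
    c[-1] = 1.0
    return xs, c


def w2sq_to_target(
    p: WeightedSample,
    target: TargetDistribution,
    n_quad: int = 512,
    method: str = "midpoint",
) -> float:
    """W2^2 between a weighted sample and a continuous guiding law.

    ``method="midpoint"`` approximates int_0^1 (F_p^{-1}(u) - F_t^{-1}(u))^2 du
    by the midpoint rule on u_k = (k - 1/2) / n_quad, with F_p^{-1} the
    left-continuous weighted-empirical quantile function.  ``method="exact"``
    evaluates the segment-wise closed form (exact up to the closed-form
    partial expectations of the target).
    """
    if not np.isfinite(target.second_moment()):
        raise UnsupportedTargetError("target must have a finite second moment")
    xs, c = _sorted_cumulative(p)
    if method == "exact":
        return _w2sq_exact_sorted(xs, c, target)[0]
    if method != "midpoint":
        raise ValueError(f"unknown method {method!r}")
    if n_quad < 2:
        raise ValueError("n_quad must be >= 2")
    u = (np.arange(n_quad) + 0.5) / n_quad
    idx = np.minimum(np.searchsorted(c, u, side="left"), xs.size - 1)
    diff = xs[idx] - target.ppf(u)
    return float(np.mean(diff**2))


def _w2sq_exact_sorted(xs, c, target) -> tuple[float, np.ndarray]:
    """Segment-exact W2^2 and its gradient w.r.t. the cumulative weights.

    ``c`` are cumulative weights of the sorted atoms ``xs`` (c[-1] == 1).
    Returns (value, dW2^2/dc) with the last gradient entry zero (c_n fixed).
    """
    g1 = target.quantile_integral(c)
    dg1 = np.diff(np.concatenate(([0.0], g1)))
    dc = np.diff(np.concatenate(([0.0], c)))
    value = float(np.sum(xs**2 * dc - 2.0 * xs * dg1) + target.second_moment())
    grad_c = np.zeros_like(c)
    if xs.size > 1:
        cc = np.clip(c[:-1], 1e-15, 1.0 - 1e-15)
        qc = np.asarray(target.ppf(cc), dtype=float)
        grad_c[:-1] = (xs[:-1] - xs[1:]) * (xs[:-1] + xs[1:] - 2.0 * qc)
    return value, grad_c


# ---------------------------------------------------------------------------
# Max-entropy simplex solver (entropic mirror ascent)
# ---------------------------------------------------------------------------


def _moment_matrix(atoms: np.ndarray, moment) -> np.ndarray | None:
    if moment is None:
        return None
    if callable(moment):
        g = np.asarray(moment(atoms), dtype=float)
    else:
        g = np.asarray(moment, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[0] != atoms.size:
        raise ValueError("moment constraint must supply one row per atom")
    return g


def _check_hull(g: np.ndarray) -> bool:
    """True iff the origin lies in the convex hull of the rows of g."""
    if g.shape[1] == 1:
        col = g[:, 0]
        return bool(col.min() <= 1e-12 and col.max() >= -1e-12)
    n, k = g.shape
    res = optimize.linprog(
        c=np.zeros(n),
        A_eq=np.vstack([np.ones((1, n)), g.T]),
        b_eq=np.concatenate(([1.0], np.zeros(k))),
        bounds=[(0.0, None)] * n,
        method="highs",
    )
    return bool(res.status == 0)


def _tilt_project(v: np.ndarray, g: np.ndarray | None, xi0=None):
    """Normalize v onto the simplex and tilt it onto {w : g' w = 0}.

    Finds xi minimizing log sum_i v_i exp(g_i . xi) (convex); the minimizer
    makes the tilted weights satisfy the moment conditions exactly.
    Returns (weights, xi).
    """
    logv = np.log(np.clip(v, 1e-300, None))
    if g is None:
        w = np.exp(logv - logv.max())
        return w / w.sum(), None
    k = g.shape[1]
    xi = np.zeros(k) if xi0 is None else np.array(xi0, dtype=float)
    for _ in range(100):
        t = logv + g @ xi
        t -= t.max()
        w = np.exp(t)
        w /= w.sum()
        grad = g.T @ w
        if np.max(np.abs(grad)) < 1e-13 * max(1.0, float(np.max(np.abs(g)))):
            break
        hess = (g * w[:, None]).T @ g - np.outer(grad, grad)
        try:
            step = np.linalg.solve(hess + 1e-14 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = grad
        # damped Newton with step-size cap
        ns = float(np.linalg.norm(step))
        if ns > 50.0:
            step *= 50.0 / ns
        xi = xi - step
    t = logv + g @ xi
    t -= t.max()
    w = np.exp(t)
    return w / w.sum(), xi


def _stationarity(w, grad, g):
    """KKT residual: project grad onto span{1, g-columns} under weights w."""
    cols = [np.ones_like(w)]
    if g is not None:
        cols.extend(g.T)
    a = np.column_stack(cols)
    aw = a * w[:, None]
    beta, *_ = np.linalg.lstsq(aw.T @ a, aw.T @ grad, rcond=None)
    resid = grad - a @ beta
    interior = float(np.max(w * np.abs(resid)))
    mask = w <= 10.0 * _FLOOR
    boundary = float(np.max(resid[mask])) if mask.any() else 0.0
    return max(interior, max(boundary, 0.0) * 1e-3)


def _solve_simplex(
    atoms: np.ndarray,
    target,
    ent_coef: float,
    w2_coef: float,
    linear: np.ndarray | None = None,
    moment: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 4000,
    n_restarts: int = 5,
    seed: int = 20240311,
):
    """Maximize ent_coef*H(w) - w2_coef*W2^2(w; target) + linear.w on the simplex.

    Entropic mirror ascent with Armijo backtracking; the optional moment
    hyperplane g'w = 0 is maintained exactly at every iterate via an
    exponential tilt.  Returns (weights, objective, w2sq, converged, iters,
    stationarity).
    """
    n = atoms.size
    order = np.argsort(atoms, kind="stable")
    inv_order = np.argsort(order)
    xs = atoms[order]

    def f_and_grad(w):
        obj = 0.0
        grad = np.zeros(n)
        if ent_coef != 0.0:
            logw = np.log(np.clip(w, _FLOOR, None))
            obj += ent_coef * float(-(w * logw).sum())
            grad += ent_coef * (-logw - 1.0)
        w2 = 0.0
        if target is not None:
            c = np.cumsum(w[order])
            c[-1] = 1.0
            w2, gc = _w2sq_exact_sorted(xs, c, target)
            if w2_coef != 0.0:
                gw_sorted = np.cumsum(gc[::-1])[::-1]
                obj += -w2_coef * w2
                grad += -w2_coef * gw_sorted[inv_order]
        if linear is not None:
            obj += float(linear @ w)
            grad += linear
        return obj, grad, w2

    if moment is not None and not _check_hull(moment):
        raise InfeasibleConstraintError(
            "moment constraint infeasible: the convex hull of the constraint "
            "columns does not contain the origin"
        )

    def run(w_start):
        w, xi = _tilt_project(np.clip(w_start, _FLOOR, None), moment)
        step = 1.0
        obj, grad, w2 = f_and_grad(w)
        stat = _stationarity(w, grad, moment)
        it = 0
        window_obj = obj
        while it < max_iter and stat > tol:
            it += 1
            gshift = grad - grad.max()
            s = step
            improved = False
            for _ in range(40):
                v = w * np.exp(np.clip(s * gshift, -700, 50))
                w_try, xi = _tilt_project(np.clip(v, _FLOOR, None), moment, xi)
                w_try = np.clip(w_try, _FLOOR, None)
                w_try /= w_try.sum()
                obj_try, grad_try, w2_try = f_and_grad(w_try)
                if obj_try >= obj - 1e-15 * max(1.0, abs(obj)):
                    improved = obj_try > obj
                    w, obj, grad, w2 = w_try, obj_try, grad_try, w2_try
                    break
                s *= 0.5
            else:
                break
            step = min(s * 1.6, 1e6) if improved else max(s * 0.5, 1e-14)
            if not improved and s <= 1e-13:
                break
            # stationarity check and stall detection every 10 iterations
            if it % 10 == 0 or it == max_iter:
                stat = _stationarity(w, grad, moment)
                if obj - window_obj < 1e-13 * max(1.0, abs(obj)):
                    break  # no measurable progress over the window
                window_obj = obj
        stat = _stationarity(w, grad, moment)
        return w, obj, w2, stat, it

    starts = [np.full(n, 1.0 / n) if w0 is None else np.asarray(w0, dtype=float)]
    best = None
    total_it = 0
    rng = np.random.default_rng(seed)
    for attempt in range(1 + n_restarts):
        w, obj, w2, stat, it = run(starts[0] if attempt == 0 else rng.dirichlet(np.ones(n)))
        total_it += it
        if best is None or obj > best[1] + 1e-12 or (stat < best[3] and obj >= best[1] - 1e-10):
            best = (w, obj, w2, stat)
        elif attempt > 0:
            break  # restart brought no improvement; further restarts will not either
        if best[3] <= max(tol, 1e-7):
            break
    w, obj, w2, stat = best
    return w, obj, w2, stat <= 1e-7, total_it, stat


def _as_target(target):
    if target is None or isinstance(target, (TargetDistribution, _DiscreteTarget)):
        return target
    if isinstance(target, WeightedSample):
        return _DiscreteTarget(target.atoms, target.weights)
    raise TypeError(f"unsupported target type {type(target)!r}")


def maxent_penalized(
    atoms,
    target,
    lam: float,
    moment_fn=None,
    tol: float = 1e-9,
) -> SimplexSolveResult:
    """Solve  max_w H_n(w) - lam * W2^2(sum w_i delta_{atoms_i}, target)
    on the simplex, optionally intersected with sum_i w_i g_i = 0."""
    atoms = np.asarray(atoms, dtype=float)
    if lam < 0.0:
        raise ValueError("lam must be nonnegative")
    target = _as_target(target)
    g = _moment_matrix(atoms, moment_fn)
    n = atoms.size

    if lam == 0.0 or target is None:
        if g is None:
            w = np.full(n, 1.0 / n)
        else:
            if not _check_hull(g):
                raise InfeasibleConstraintError(
                    "moment constraint infeasible on the simplex"
                )
            w, _ = _tilt_project(np.full(n, 1.0 / n), g)
        w2 = (
            w2sq_to_target(WeightedSample(atoms, w), target, method="exact")
            if target is not None
            else 0.0
        )
        h = entropy(w)
        return SimplexSolveResult(w, h - lam * w2, h, w2, True, 0, lam=lam, stationarity=0.0)

    w, obj, w2, conv, it, stat = _solve_simplex(
        atoms, target, ent_coef=1.0, w2_coef=lam, moment=g, tol=tol
    )
    return SimplexSolveResult(w, obj, entropy(w), w2, conv, it, lam=lam, stationarity=stat)


def maxent_constrained(
    atoms,
    target,
    eps: float,
    moment_fn=None,
    lam_max: float = 1e6,
    rel_tol: float = 1e-4,
    max_bisect: int = 64,
) -> SimplexSolveResult:
    """Primal form: max H(w) s.t. W2^2(w; target) <= eps (+ moment conditions).

    Implemented by bisection on the penalty lam of :func:`maxent_penalized`
    until the W2^2 constraint is active within relative tolerance, or slack at
    lam = 0 (in which case the unconstrained optimum is returned).
    """
    if eps < 0.0:
        raise ValueError("eps must be nonnegative")
    atoms = np.asarray(atoms, dtype=float)
    target = _as_target(target)
    g = _moment_matrix(atoms, moment_fn)

    base = maxent_penalized(atoms, target, 0.0, moment_fn=g)
    if base.w2sq <= eps:
        return base

    def solve(lam, w0):
        w, obj, w2, conv, it, stat = _solve_simplex(
            atoms, target, ent_coef=1.0, w2_coef=lam, moment=g, w0=w0
        )
        return SimplexSolveResult(
            w, entropy(w), entropy(w), w2, conv, it, lam=lam, stationarity=stat
        )

    lo, res_lo = 0.0, base
    hi = 1.0
    res_hi = solve(hi, base.weights)
    while res_hi.w2sq > eps and hi < lam_max:
        lo, res_lo = hi, res_hi
        hi = min(hi * 8.0, lam_max)
        res_hi = solve(hi, res_hi.weights)
    if res_hi.w2sq > eps * (1.0 + rel_tol) + 1e-12:
        raise InfeasibleConstraintError(
            f"eps = {eps:.6g} below the minimum achievable W2^2 "
            f"(~{res_hi.w2sq:.6g} at lam = {hi:.3g})"
        )
    best = res_hi
    for _ in range(max_bisect):
        if abs(best.w2sq - eps) <= rel_tol * max(eps, 1e-300):
            break
        mid = 0.5 * (lo + hi)
        res_mid = solve(mid, best.weights)
        if res_mid.w2sq > eps:
            lo = mid
        else:
            hi = mid
            best = res_mid
    best.objective = best.entropy
    return best


# ---------------------------------------------------------------------------
# Exponentially tilted empirical likelihood under moment conditions
# ---------------------------------------------------------------------------


def etel_moment(x, survey_w, g, theta, max_iter: int = 200):
    """ETEL weights for the moment-condition model at parameter theta.

    Solves the inner tilt  lambda(theta) = argmin_eta (1/n) sum_i
    exp(pi_i eta' g(x_i, theta))  by damped Newton and returns the tilted
    weights  w_i* = exp(pi_i lambda' g_i) / sum_j exp(pi_j lambda' g_j)
    together with sum_i log w_i*.  When the convex hull of {g(x_i, theta)}
    does not contain the origin the log-likelihood is -inf (the likelihood is
    set to zero) and the weights are None.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    pi = np.asarray(survey_w, dtype=float)
    if np.any(pi <= 0.0) or not np.all(np.isfinite(pi)):
        raise ValueError("survey weights must be strictly positive and finite")
    gm = np.asarray(g(x, theta), dtype=float)
    if gm.ndim == 1:
        gm = gm[:, None]
    if not _check_hull(gm):
        return None, -np.inf
    k = gm.shape[1]
    pg = gm * pi[:, None]
    eta = np.zeros(k)
    scale = max(1.0, float(np.max(np.abs(pg))))
    for it in range(max_iter):
        t = pg @ eta
        tmax = t.max()
        e = np.exp(t - tmax)
        phi = e.mean()
        grad = (pg * e[:, None]).mean(axis=0)
        if np.max(np.abs(grad)) <= 1e-12 * scale * phi:
            break
        hess = (pg * e[:, None]).T @ pg / n
        try:
            step = np.linalg.solve(hess + 1e-13 * phi * np.eye(k), grad)
        except np.linalg.LinAlgError:
            step = grad / max(phi, 1e-300)
        # backtracking on log phi
        logphi0 = math.log(phi) + tmax
        s = 1.0
        for _ in range(60):
            eta_try = eta - s * step
            t_try = pg @ eta_try
            m = t_try.max()
            logphi = math.log(np.exp(t_try - m).mean()) + m
            if logphi < logphi0:
                eta = eta_try
                break
            s *= 0.5
        else:
            break
    else:
        raise NumericalFailureError(
            f"ETEL inner tilt did not converge after {max_iter} iterations "
            f"(|grad| = {np.max(np.abs(grad)):.3e})"
        )
    t = pg @ eta
    t -= t.max()
    w = np.exp(t)
    w /= w.sum()
    loglik = float(np.log(np.clip(w, 1e-300, None)).sum())
    return w, loglik
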