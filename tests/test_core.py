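"""Core reweighting machinery: entropy, exact 1-D W2, simplex solvers, ETEL."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from otmaxent.core import (
    InfeasibleConstraintError,
    InvalidSimplexError,
    WeightedSample,
    entropy,
    etel_moment,
    maxent_constrained,
    maxent_penalized,
    w2sq_discrete,
    w2sq_to_target,
)
from otmaxent.distributions import TargetDistribution

from conftest import brute_w2sq, simplex_grid_3


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "weights, expected",
    [
        ([0.25, 0.25, 0.25, 0.25], math.log(4.0)),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.7, 0.3], -0.7 * math.log(0.7) - 0.3 * math.log(0.3)),
    ],
)
def test_entropy_closed_forms(weights, expected):
    assert entropy(weights) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [[-0.2, 1.2], [0.5, 0.4], [0.6, 0.6]])
def test_entropy_rejects_invalid_simplex(bad):
    with pytest.raises(InvalidSimplexError):
        entropy(bad)


@given(st.integers(2, 12), st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_entropy_bounded_by_log_m(m, seed):
    w = np.random.default_rng(seed).dirichlet(np.ones(m))
    h = entropy(w)
    assert -1e-12 <= h <= math.log(m) + 1e-12


# ---------------------------------------------------------------------------
# discrete W2^2
# ---------------------------------------------------------------------------


def test_w2sq_discrete_identity_and_point_masses(rng):
    atoms = rng.normal(size=7)
    p = WeightedSample(atoms, rng.dirichlet(np.ones(7)))
    assert w2sq_discrete(p, p) == pytest.approx(0.0, abs=1e-12)
    a, b = 1.3, -2.1
    pa = WeightedSample(np.array([a]), np.array([1.0]))
    pb = WeightedSample(np.array([b]), np.array([1.0]))
    assert w2sq_discrete(pa, pb) == pytest.approx((a - b) ** 2, rel=1e-12)


def test_w2sq_discrete_matches_brute_force_grid():
    p = WeightedSample(np.array([0.0, 1.0]), np.array([0.5, 0.5]))
    q = WeightedSample(np.array([0.0, 1.0]), np.array([0.25, 0.75]))
    expected = brute_w2sq(p.atoms, p.weights, q.atoms, q.weights)
    assert w2sq_discrete(p, q) == pytest.approx(expected, abs=1e-5)


@given(st.integers(0, 2**31 - 1), st.integers(2, 9), st.integers(2, 9))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_w2sq_discrete_symmetric_and_matches_oracle(seed, m, k):
    g = np.random.default_rng(seed)
    p = WeightedSample(g.normal(size=m), g.dirichlet(np.ones(m)))
    q = WeightedSample(g.normal(size=k), g.dirichlet(np.ones(k)))
    d_pq = w2sq_discrete(p, q)
    assert d_pq == pytest.approx(w2sq_discrete(q, p), rel=1e-10, abs=1e-12)
    assert d_pq == pytest.approx(
        brute_w2sq(p.atoms, p.weights, q.atoms, q.weights, n_grid=200_000),
        rel=2e-3,
        abs=1e-4,
    )


def test_w2sq_discrete_zero_for_equal_measures_with_split_atoms():
    # the same measure written with duplicated atoms must be at distance zero
    p = WeightedSample(np.array([0.0, 2.0]), np.array([0.5, 0.5]))
    q = WeightedSample(np.array([2.0, 0.0, 0.0]), np.array([0.5, 0.2, 0.3]))
    assert w2sq_discrete(p, q) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# W2^2 to a continuous target
# ---------------------------------------------------------------------------


def test_point_mass_at_target_mean_gives_variance():
    target = TargetDistribution.normal(1.7, 2.3)
    p = WeightedSample(np.array([1.7]), np.array([1.0]))
    assert w2sq_to_target(p, target, n_quad=200_000) == pytest.approx(2.3, rel=1e-3)
    assert w2sq_to_target(p, target, method="exact") == pytest.approx(2.3, rel=1e-10)


def test_self_discretization_transport_vanishes():
    target = TargetDistribution.normal(0.0, 1.0)
    prev = None
    for n in (64, 256, 1024):
        u = (np.arange(n) + 0.5) / n
        p = WeightedSample.uniform(target.ppf(u))
        d = w2sq_to_target(p, target, n_quad=8192)
        assert d < 5.0 / n
        if prev is not None:
            assert d < prev
        prev = d


def test_three_atom_target_distance_matches_quadrature_oracle():
    atoms = np.array([-1.0, 0.0, 2.0])
    weights = np.array([0.2, 0.5, 0.3])
    target = TargetDistribution.normal(0.0, 1.0)
    # segment-wise adaptive quadrature of (x_(i) - F^{-1}(u))^2
    edges = [0.0, 0.2, 0.7, 1.0]
    expected = 0.0
    for x, (lo, hi) in zip(atoms, zip(edges[:-1], edges[1:])):
        val, _ = integrate.quad(lambda u, x=x: (x - stats.norm.ppf(u)) ** 2, lo, hi)
        expected += val
    assert w2sq_to_target(WeightedSample(atoms, weights), target, n_quad=4096) == pytest.approx(
        expected, rel=5e-3
    )
    assert w2sq_to_target(
        WeightedSample(atoms, weights), target, method="exact"
    ) == pytest.approx(expected, rel=1e-8)


def test_discrete_continuous_consistency():
    # replacing the target by its own n_quad-atom quantile discretization
    # must reproduce w2sq_discrete up to O(1/n_quad)
    target = TargetDistribution.normal(0.5, 2.0)
    p = WeightedSample(np.array([-1.0, 0.3, 1.1, 4.0]), np.array([0.1, 0.4, 0.3, 0.2]))
    for n_quad in (256, 2048):
        u = (np.arange(n_quad) + 0.5) / n_quad
        q = WeightedSample.uniform(np.asarray(target.ppf(u)))
        d_cont = w2sq_to_target(p, target, n_quad=n_quad)
        d_disc = w2sq_discrete(p, q)
        assert abs(d_cont - d_disc) < 20.0 / n_quad


# ---------------------------------------------------------------------------
# penalized / constrained max-entropy solvers
# ---------------------------------------------------------------------------


def test_zero_penalty_returns_uniform():
    res = maxent_penalized(np.array([0.0, 1.0, 5.0]), None, lam=0.0)
    np.testing.assert_allclose(res.weights, 1.0 / 3.0)
    assert res.converged and res.entropy == pytest.approx(math.log(3.0))


def test_zero_penalty_with_centered_moment_keeps_uniform():
    atoms = np.array([-1.0, 0.0, 2.0, 3.0])
    res = maxent_penalized(atoms, None, lam=0.0, moment_fn=lambda x: x - x.mean())
    np.testing.assert_allclose(res.weights, 0.25, atol=1e-10)


def test_penalized_matches_simplex_grid_oracle():
    atoms = np.array([-1.0, 0.0, 3.0])
    target = TargetDistribution.normal(0.0, 1.0)
    lam = 5.0
    grid = simplex_grid_3(step=1e-3)
    # vectorized objective over the grid (atoms already sorted)
    c1 = grid[:, 0]
    c2 = grid[:, 0] + grid[:, 1]
    g1_1 = np.asarray(target.quantile_integral(c1))
    g1_2 = np.asarray(target.quantile_integral(c2))
    w2 = (
        atoms[0] ** 2 * c1
        + atoms[1] ** 2 * (c2 - c1)
        + atoms[2] ** 2 * (1.0 - c2)
        - 2.0 * (atoms[0] * g1_1 + atoms[1] * (g1_2 - g1_1) + atoms[2] * (0.0 - g1_2))
        + target.second_moment()
    )
    wl = np.clip(grid, 1e-300, None)
    ent = -(wl * np.log(wl)).sum(axis=1)
    objective = ent - lam * w2
    w_star = grid[np.argmax(objective)]
    res = maxent_penalized(atoms, target, lam)
    assert res.converged
    assert np.max(np.abs(res.weights - w_star)) < 2e-3


def test_infeasible_moment_constraint_raises():
    with pytest.raises(InfeasibleConstraintError):
        maxent_penalized(np.array([1.0, 2.0, 3.0]), None, lam=0.0, moment_fn=lambda x: x)


def test_constrained_slack_returns_uniform():
    atoms = np.array([-1.0, 0.0, 3.0])
    target = TargetDistribution.normal(0.0, 1.0)
    u = WeightedSample.uniform(atoms)
    d0 = w2sq_to_target(u, target, method="exact")
    for eps in (d0 + 1.0, np.inf):
        res = maxent_constrained(atoms, target, eps)
        np.testing.assert_allclose(res.weights, 1.0 / 3.0, atol=1e-10)


def test_constrained_active_at_half_uniform_distance():
    atoms = np.array([-1.0, 0.0, 3.0])
    target = TargetDistribution.normal(0.0, 1.0)
    eps = 0.5 * w2sq_to_target(WeightedSample.uniform(atoms), target, method="exact")
    res = maxent_constrained(atoms, target, eps)
    assert abs(res.w2sq - eps) <= 1.5e-4 * eps
    # entropy must match the best grid point satisfying the constraint
    grid = simplex_grid_3(step=2e-3)
    c1, c2 = grid[:, 0], grid[:, 0] + grid[:, 1]
    g1_1 = np.asarray(target.quantile_integral(c1))
    g1_2 = np.asarray(target.quantile_integral(c2))
    w2 = (
        atoms[0] ** 2 * c1
        + atoms[1] ** 2 * (c2 - c1)
        + atoms[2] ** 2 * (1.0 - c2)
        - 2.0 * (atoms[0] * g1_1 + atoms[1] * (g1_2 - g1_1) - atoms[2] * g1_2)
        + target.second_moment()
    )
    wl = np.clip(grid, 1e-300, None)
    ent = -(wl * np.log(wl)).sum(axis=1)
    feasible = w2 <= eps * (1.0 + 1e-3)
    assert res.entropy == pytest.approx(ent[feasible].max(), abs=5e-4)


def test_constrained_infeasible_eps_reports_minimum():
    atoms = np.array([10.0, 11.0])
    target = TargetDistribution.normal(0.0, 1.0)
    with pytest.raises(InfeasibleConstraintError, match="minimum"):
        maxent_constrained(atoms, target, eps=1e-6)


def test_lambda_monotonicity_of_entropy_and_distance():
    atoms = np.array([-2.0, -0.5, 0.7, 3.0])
    target = TargetDistribution.normal(0.0, 1.0)
    prev = None
    for lam in (0.0, 0.3, 1.0, 3.0, 10.0, 100.0):
        res = maxent_penalized(atoms, target, lam)
        if prev is not None:
            assert res.w2sq <= prev.w2sq + 1e-6
            assert res.entropy <= prev.entropy + 1e-6
        prev = res


def test_objective_concavity_certificate(rng):
    atoms = np.sort(rng.normal(size=6))
    target = TargetDistribution.normal(0.0, 1.0)
    lam = 2.0

    def objective(w):
        return entropy(w) - lam * w2sq_to_target(
            WeightedSample(atoms, w), target, method="exact"
        )

    for _ in range(25):
        w1 = rng.dirichlet(np.ones(6))
        w2 = rng.dirichlet(np.ones(6))
        t = rng.uniform(0.05, 0.95)
        mix = t * w1 + (1 - t) * w2
        assert objective(mix) >= t * objective(w1) + (1 - t) * objective(w2) - 1e-8


def test_duality_consistency_constrained_vs_penalized():
    atoms = np.array([-1.5, 0.2, 0.9, 2.5])
    target = TargetDistribution.normal(0.0, 1.0)
    eps = 0.4 * w2sq_to_target(WeightedSample.uniform(atoms), target, method="exact")
    rc = maxent_constrained(atoms, target, eps)
    rp = maxent_penalized(atoms, target, rc.lam)
    assert np.max(np.abs(rc.weights - rp.weights)) < 1e-5


def test_solve_results_respect_entropy_bound():
    atoms = np.array([-1.0, 0.0, 1.0, 4.0])
    target = TargetDistribution.normal(0.0, 1.0)
    for lam in (0.0, 1.0, 50.0):
        res = maxent_penalized(atoms, target, lam)
        assert -1e-10 <= res.entropy <= math.log(atoms.size) + 1e-10
        if lam == 0.0:
            assert res.entropy == pytest.approx(math.log(atoms.size), abs=1e-8)


# ---------------------------------------------------------------------------
# exponentially tilted empirical likelihood
# ---------------------------------------------------------------------------


def test_etel_uniform_when_weighted_moment_is_stationary():
    x = np.array([-2.0, -1.0, 1.0, 2.0])
    pi = np.array([1.0, 2.0, 2.0, 1.0])
    w, ll = etel_moment(x, pi, lambda x, t: x - t, theta=0.0)
    np.testing.assert_allclose(w, 0.25, atol=1e-8)
    assert ll == pytest.approx(4 * math.log(0.25), abs=1e-6)


def test_etel_convex_hull_violation_gives_minus_infinity():
    x = np.array([1.0, 2.0, 3.0])
    w, ll = etel_moment(x, np.ones(3), lambda x, t: x - t, theta=0.5)
    assert w is None and ll == -np.inf


def test_etel_matches_fine_grid_tilt_oracle():
    x = np.array([0.0, 1.0, 2.0, 5.0])
    pi = np.ones(4)
    g = x - 1.0
    etas = np.linspace(-5.0, 5.0, 2_000_001)
    phi = np.exp(np.outer(etas, g)).sum(axis=1)
    eta_star = etas[np.argmin(phi)]
    w_expected = np.exp(eta_star * g)
    w_expected /= w_expected.sum()
    w, _ = etel_moment(x, pi, lambda x, t: x - t, theta=1.0)
    np.testing.assert_allclose(w, w_expected, atol=2e-5)
    assert np.dot(w, g) == pytest.approx(0.0, abs=1e-8)
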