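"""Demographic parity in the Wasserstein metric: diagnostics, both schemes,
fair prediction."""

import numpy as np
import pytest

from otmaxent.core import entropy
from otmaxent.fairness import (
    FairnessData,
    fair_predict,
    fit_in_model,
    fit_two_step,
    parity_w2sq,
)
from otmaxent.synthetic import FairSimConfig, gen_fairness

from conftest import brute_w2sq


@pytest.fixture(scope="module")
def cohort():
    # shifted-T cohort: clearly discrepant fitted-value distributions
    return gen_fairness(FairSimConfig(n_s=80, n_t=80, seed=3))


def _design(x):
    return np.column_stack([np.ones(x.shape[0]), x])


def _group_ols_fits(data):
    ms, mt = data.masks()
    th_s, *_ = np.linalg.lstsq(_design(data.x[ms]), data.y[ms], rcond=None)
    th_t, *_ = np.linalg.lstsq(_design(data.x[mt]), data.y[mt], rcond=None)
    hs = _design(data.x[ms]) @ th_s
    ht = _design(data.x[mt]) @ th_t
    return th_s, th_t, hs, ht


# ---------------------------------------------------------------------------
# parity diagnostic
# ---------------------------------------------------------------------------


def test_parity_zero_for_identical_fitted_values():
    v = np.array([0.3, 1.0, -2.0])
    assert parity_w2sq(v, v, np.full(3, 1 / 3)) == pytest.approx(0.0, abs=1e-12)


def test_parity_point_masses_squared_gap():
    s = np.full(4, 2.0)
    t = np.full(3, -1.5)
    assert parity_w2sq(s, t, np.full(3, 1 / 3)) == pytest.approx(3.5**2, rel=1e-12)


def test_parity_matches_merged_breakpoint_oracle():
    s = np.array([0.0, 1.0, 3.0])
    t = np.array([0.5, 2.0])
    w = np.array([0.3, 0.7])
    expected = brute_w2sq(s, np.full(3, 1 / 3), t, w, n_grid=300_000)
    assert parity_w2sq(s, t, w) == pytest.approx(expected, rel=1e-3)


# ---------------------------------------------------------------------------
# two-step scheme
# ---------------------------------------------------------------------------


def test_two_step_at_lambda_one_keeps_ols_and_uniform(cohort):
    fit = fit_two_step(cohort, 1.0)
    th_s, th_t, _, _ = _group_ols_fits(cohort)
    np.testing.assert_allclose(fit.weights_t, 1.0 / cohort.n_t, atol=1e-12)
    np.testing.assert_allclose(fit.theta_s, th_s, atol=1e-9)
    np.testing.assert_allclose(fit.theta_t, th_t, atol=1e-9)


def test_two_step_at_lambda_zero_improves_parity(cohort):
    fit = fit_two_step(cohort, 0.0)
    _, _, hs, ht = _group_ols_fits(cohort)
    unconstrained = parity_w2sq(hs, ht, np.full(ht.size, 1.0 / ht.size))
    assert fit.parity_w2sq <= unconstrained + 1e-9


def test_two_step_weights_match_one_dimensional_grid_oracle():
    # n_T = 2: the step-2 solve is a 1-D problem over w1 in [0, 1]
    x = np.array([[0.0], [1.0], [2.0], [0.5], [1.5]])
    y = np.array([0.1, 1.2, 1.9, 2.1, 3.4])
    a = np.array(["S", "S", "S", "T", "T"])
    data = FairnessData(x, y, a)
    lam = 0.4
    fit = fit_two_step(data, lam)
    ms, mt = data.masks()
    hs = _design(data.x[ms]) @ fit.theta_s
    ht = _design(data.x[mt]) @ fit.theta_t
    w1 = np.linspace(1e-9, 1 - 1e-9, 20001)
    vals = []
    for w in w1:
        wv = np.array([w, 1.0 - w])
        vals.append(
            -(1 - lam) * parity_w2sq(hs, ht, wv) + lam * entropy(wv)
        )
    w_star = w1[int(np.argmax(vals))]
    assert fit.weights_t[0] == pytest.approx(w_star, abs=2e-3)


# ---------------------------------------------------------------------------
# in-model scheme
# ---------------------------------------------------------------------------


def test_in_model_objective_ascends_every_sweep(cohort):
    fit = fit_in_model(cohort, 0.25)
    assert fit.objective_path is not None
    assert np.all(np.diff(fit.objective_path) >= -1e-9)


def test_in_model_at_lambda_one_weights_are_loss_softmax(cohort):
    fit = fit_in_model(cohort, 1.0)
    ms, mt = cohort.masks()
    rt = cohort.y[mt] - _design(cohort.x[mt]) @ fit.theta_t
    # stationarity of H(w) - sum w_i l_i on the simplex
    expected = np.exp(-(rt**2) / (2.0 * fit.sigma2))
    expected /= expected.sum()
    np.testing.assert_allclose(fit.weights_t, expected, atol=5e-4)


def test_scheme_ordering_unconstrained_two_step_in_model(cohort):
    _, _, hs, ht = _group_ols_fits(cohort)
    unconstrained = parity_w2sq(hs, ht, np.full(ht.size, 1.0 / ht.size))
    two_step = fit_two_step(cohort, 0.0).parity_w2sq
    in_model = fit_in_model(cohort, 0.0).parity_w2sq
    assert unconstrained >= two_step - 1e-9
    assert two_step >= in_model - 1e-9
    # the joint scheme reduces the discrepancy by a clear margin
    assert in_model < 0.5 * two_step


def test_parity_entropy_tradeoff_along_lambda_grid(cohort):
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    fits = [fit_two_step(cohort, lam) for lam in grid]
    pw = [f.parity_w2sq for f in fits]
    ent = [entropy(f.weights_t) for f in fits]
    assert all(b >= a - 1e-6 for a, b in zip(pw, pw[1:]))
    assert all(b >= a - 1e-6 for a, b in zip(ent, ent[1:]))


def test_rank_deficient_design_is_reported():
    x = np.column_stack([np.ones(12), np.ones(12)])
    y = np.arange(12.0)
    a = np.array(["S"] * 6 + ["T"] * 6)
    with pytest.raises(ValueError, match="collinear"):
        fit_two_step(FairnessData(x, y, a), 0.5)


# ---------------------------------------------------------------------------
# fair prediction
# ---------------------------------------------------------------------------


def test_kernel_prediction_localizes_to_training_point(cohort):
    fit = fit_two_step(cohort, 1.0)  # uniform weights
    ms, mt = cohort.masks()
    xt, yt = cohort.x[mt], cohort.y[mt]
    pred = fair_predict(fit, xt[4], "T", bandwidth=1e-4)
    assert pred == pytest.approx(yt[4], abs=1e-6)


def test_group_s_prediction_is_linear_and_ignores_weights(cohort):
    fit = fit_two_step(cohort, 0.0)
    x_new = np.array([0.2, -0.3, 0.5])
    expected = float(np.concatenate(([1.0], x_new)) @ fit.theta_s)
    assert fair_predict(fit, x_new, "S") == pytest.approx(expected, abs=1e-12)
    fit.weights_t = np.roll(fit.weights_t, 3)
    assert fair_predict(fit, x_new, "S") == pytest.approx(expected, abs=1e-12)


def test_weighted_kernel_formula_by_hand():
    x = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]])
    y = np.array([0.0, 1.0, 2.0, 1.0, 2.0, 3.0])
    a = np.array(["S"] * 3 + ["T"] * 3)
    data = FairnessData(x, y, a)
    fit = fit_two_step(data, 1.0)
    fit.weights_t = np.array([0.5, 0.3, 0.2])
    h, x_new = 0.8, np.array([0.7])
    k = np.exp(-0.5 * ((np.array([0.0, 1.0, 2.0]) - 0.7) / h) ** 2) * fit.weights_t
    expected = float(k @ np.array([1.0, 2.0, 3.0]) / k.sum())
    assert fair_predict(fit, x_new, "T", bandwidth=h) == pytest.approx(expected, abs=1e-12)


def test_prediction_dimension_mismatch_rejected(cohort):
    fit = fit_two_step(cohort, 0.5)
    with pytest.raises(ValueError, match="length"):
        fair_predict(fit, np.array([1.0, 2.0]), "T")
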