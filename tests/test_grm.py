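"""GRM engine: probabilities, EM estimation, curves, information, scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclpipe.grm import test_curves as grm_test_curves  # noqa: N813
from sclpipe.grm import (
    GRMParams,
    category_probabilities,
    eap_scores,
    empirical_marginal_reliability,
    fit_grm,
    information,
    make_quadrature,
    marginal_loglik,
    person_item_map,
)
from sclpipe.synthetic import DEFAULT_SLOPES, DEFAULT_THRESHOLDS, simulate_grm


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def hand_coded_probs(a, b, theta):
    """Independent direct evaluation of Samejima category probabilities."""
    pstar = np.concatenate([[1.0], _logistic(a * (theta - b)), [0.0]])
    return pstar[:-1] - pstar[1:]


def test_cumulative_probability_midpoint():
    p = GRMParams(a=[1.7], b=[[-1.0, 0.0, 1.0, 2.0]])
    probs = category_probabilities(p, 0.0)         # theta = b_2
    assert probs[0, 2:].sum() == pytest.approx(0.5, abs=1e-12)


def test_zero_slope_flat_probabilities():
    p = GRMParams(a=[0.0], b=[[-1.0, 0.0, 1.0, 2.0]])
    for theta in (-3.0, 0.0, 3.0):
        probs = category_probabilities(p, theta)
        assert np.allclose(np.cumsum(probs[0][::-1])[::-1][1:], 0.5)


def test_probabilities_match_hand_coded_oracle():
    a, b = 2.0, np.array([-1.0, 0.0, 1.0, 2.0])
    p = GRMParams(a=[a], b=[b])
    ours = category_probabilities(p, 0.0)[0]
    assert np.abs(ours - hand_coded_probs(a, b, 0.0)).max() < 1e-12


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.floats(-4, 4), st.floats(0.3, 4.0))
def test_probabilities_sum_to_one(theta, a):
    p = GRMParams(a=[a] * 3, b=DEFAULT_THRESHOLDS[:3])
    probs = category_probabilities(p, theta)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
    assert (probs >= 0).all()


def test_em_matches_bruteforce_marginal_likelihood():
    """EM's reported log-likelihood equals direct per-person quadrature."""
    x = simulate_grm((DEFAULT_SLOPES[:3], DEFAULT_THRESHOLDS[:3]), 50, seed=9)
    fit = fit_grm(x, compute_se=False)
    nodes, w = fit.grid.nodes, fit.grid.weights
    total = 0.0
    for row in x:                      # independent brute-force evaluation
        lik_nodes = np.ones(nodes.size)
        for j, cat in enumerate(row):
            pstar = np.concatenate([
                np.ones((nodes.size, 1)),
                _logistic(fit.params.a[j] * (nodes[:, None] - fit.params.b[j][None, :])),
                np.zeros((nodes.size, 1))], axis=1)
            probs = pstar[:, :-1] - pstar[:, 1:]
            lik_nodes *= probs[:, cat]
        total += np.log((lik_nodes * w).sum())
    assert fit.loglik == pytest.approx(total, abs=1e-8)
    assert marginal_loglik(fit.params, x, grid=fit.grid) == pytest.approx(total, abs=1e-8)


def test_em_loglik_monotone(grm_fit_3000):
    assert np.all(np.diff(grm_fit_3000.loglik_path) >= -1e-8)
    assert grm_fit_3000.converged


def test_parameter_recovery(grm_fit_3000, uni3000):
    rmse_a = np.sqrt(np.mean((grm_fit_3000.params.a - uni3000["a"]) ** 2))
    rmse_b = np.sqrt(np.mean((grm_fit_3000.params.b - uni3000["b"]) ** 2))
    assert rmse_a < 0.15
    assert rmse_b < 0.12


def test_fit_invariant_to_row_order(uni3000):
    x = uni3000["responses"][:600]
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(x))
    f1 = fit_grm(x, compute_se=False)
    f2 = fit_grm(x[perm], compute_se=False)
    assert np.allclose(f1.params.a, f2.params.a, atol=1e-8)
    assert np.allclose(f1.params.b, f2.params.b, atol=1e-8)


def test_fit_preconditions():
    with pytest.raises(ValueError, match="more persons"):
        fit_grm(np.zeros((3, 8), dtype=int))
    x = np.ones((50, 2), dtype=int)
    with pytest.raises(ValueError, match="observed categories"):
        fit_grm(x)


def test_tcc_limits_and_monotonicity():
    p = GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS)
    curves = grm_test_curves(p, np.array([-40.0, 40.0]))
    assert curves["tcc"][0] == pytest.approx(0.0, abs=1e-8)
    assert curves["tcc"][1] == pytest.approx(32.0, abs=1e-8)
    dense = grm_test_curves(p)
    assert np.all(np.diff(dense["tcc"]) > 0)


def test_single_item_expected_score_oracle():
    a, b = 1.5, np.array([-1.0, 0.0, 1.0, 2.0])
    p = GRMParams(a=[a], b=[b])
    expected = (np.arange(5) * hand_coded_probs(a, b, 0.0)).sum()
    assert grm_test_curves(p, np.array([0.0]))["icc"][0, 0] == pytest.approx(expected, abs=1e-12)


def test_information_properties():
    p0 = GRMParams(a=[0.0, 1.5], b=DEFAULT_THRESHOLDS[:2])
    info = information(p0)
    assert np.allclose(info["iif"][:, 0], 0.0)
    assert np.allclose(info["tif"], info["iif"].sum(axis=1))
    assert (info["iif"] >= 0).all()
    # independent direct evaluation at one point
    a, b = 1.5, DEFAULT_THRESHOLDS[1]
    theta = 0.4
    pstar = _logistic(a * (theta - b))
    u = np.concatenate([[0.0], pstar * (1 - pstar), [0.0]])
    probs = hand_coded_probs(a, b, theta)
    direct = ((a * (u[:-1] - u[1:])) ** 2 / probs).sum()
    got = information(p0, np.array([theta]))["iif"][0, 1]
    assert got == pytest.approx(direct, abs=1e-12)


def test_eap_dense_grid_oracle():
    """EAP equals a brute-force posterior mean on a 10,001-point grid."""
    x = simulate_grm((DEFAULT_SLOPES[:3], DEFAULT_THRESHOLDS[:3]), 30, seed=4)
    grid = make_quadrature(10_001, 6.0)
    fit = fit_grm(x, grid=grid, compute_se=False, max_cycles=3)
    scores = eap_scores(fit)
    nodes, w = grid.nodes, grid.weights
    for i in [0, 7, 19]:
        lik = np.ones(nodes.size)
        for j, cat in enumerate(x[i]):
            pstar = np.concatenate([
                np.ones((nodes.size, 1)),
                _logistic(fit.params.a[j] * (nodes[:, None] - fit.params.b[j][None, :])),
                np.zeros((nodes.size, 1))], axis=1)
            lik *= (pstar[:, :-1] - pstar[:, 1:])[:, cat]
        post = lik * w
        post /= post.sum()
        assert scores["theta"][i] == pytest.approx(float(post @ nodes), abs=1e-6)


def test_eap_monotone_in_pattern():
    x = simulate_grm((DEFAULT_SLOPES, DEFAULT_THRESHOLDS), 400, seed=13)
    x[0] = 4                             # all max categories
    fit = fit_grm(x, compute_se=False)
    scores = eap_scores(fit)
    others = ~np.all(x == 4, axis=1)
    assert scores["theta"][0] > scores["theta"][others].max()


def test_eap_all_missing_row_gets_prior():
    x = simulate_grm((DEFAULT_SLOPES[:3], DEFAULT_THRESHOLDS[:3]), 60, seed=8)
    x[0] = -1
    fit = fit_grm(x[:], compute_se=False)
    scores = eap_scores(fit)
    assert scores["all_missing"][0]
    assert scores["theta"][0] == pytest.approx(0.0, abs=1e-6)
    assert scores["psd"][0] == pytest.approx(1.0, abs=0.01)


def test_reliability_range_and_limits(grm_fit_3000):
    rho = empirical_marginal_reliability(grm_fit_3000)
    assert 0.75 <= rho <= 0.90          # short symptom scales land here
    # steep slopes push reliability toward 1
    x = simulate_grm((np.full(8, 6.0), DEFAULT_THRESHOLDS), 800, seed=3)
    fit_hi = fit_grm(x, compute_se=False)
    assert empirical_marginal_reliability(fit_hi) > rho


def test_person_item_map(grm_fit_3000):
    wm = person_item_map(grm_fit_3000)
    scores = eap_scores(grm_fit_3000)
    lo, hi = wm["theta_range"]
    assert lo <= scores["theta"].min() and hi >= scores["theta"].max()
    assert lo <= grm_fit_3000.params.b.min() and hi >= grm_fit_3000.params.b.max()
    for th in wm["thresholds"].values():
        assert np.all(np.diff(th) > 0)
    assert wm["hist"].sum() == grm_fit_3000.n_persons
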