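"""Alignment optimization, invariance flagging, R2 indices, MC stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclpipe.alignment import (
    AlignmentResult,
    _total_loss,
    _transform,
    align,
    aligned_loglik,
    alignment_stability_mc,
    component_loss,
    flag_invariance,
    invariance_r2,
)
from sclpipe.grm import GRMFit, GRMParams, make_quadrature
from sclpipe.synthetic import DEFAULT_SLOPES, DEFAULT_THRESHOLDS


def test_component_loss_values():
    assert component_loss(0.0) == pytest.approx(0.1, abs=1e-15)
    assert component_loss(1.0) == pytest.approx(1.0001 ** 0.25, abs=1e-12)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(-10, 10, allow_nan=False))
def test_component_loss_symmetry(x):
    assert component_loss(-x) == component_loss(x)
    assert component_loss(x) >= component_loss(0.0)


def test_transform_arithmetic():
    _, b_t = _transform(np.array([[1.0]]), np.array([[[0.5]]]),
                        np.array([1.0]), np.array([4.0]))
    assert b_t[0, 0, 0] == pytest.approx(2.0)
    a_t, _ = _transform(np.array([[2.0]]), np.array([[[0.5]]]),
                        np.array([0.0]), np.array([4.0]))
    assert a_t[0, 0] == pytest.approx(1.0)


def _fake_configural(alphas, psis, n_per_group=1000, dif=None, seed=0):
    """Noise-free configural object: truth transformed into each group's
    configural parametrization (a*sqrt(psi), (b-alpha)/sqrt(psi))."""

    class Fake:
        pass

    g = len(alphas)
    fake = Fake()
    fake.level = "configural"
    fake.group_names = [f"G{i + 1}" for i in range(g)]
    fake.params = []
    fake.weights = [np.ones(n_per_group) for _ in range(g)]
    fake.group_fits = []
    for i in range(g):
        a = DEFAULT_SLOPES * np.sqrt(psis[i])
        b = (DEFAULT_THRESHOLDS - alphas[i]) / np.sqrt(psis[i])
        if dif:
            b = b.copy()
            for (item, kk, grp, off) in dif:
                if grp == i:
                    b[item, kk] += off
        p = GRMParams(a=a, b=b)
        fake.params.append(p)
        fit = Fake()
        fit.se_a = np.full(8, 0.05)
        fit.se_b = np.full((8, 4), 0.05)
        fake.group_fits.append(fit)
    return fake


def test_invariant_case_exact_recovery():
    """Pure (alpha, psi) differences: alignment recovers them and the
    aligned parameters coincide across groups."""
    alphas = np.array([0.0, -0.3, 0.25, 0.5])
    psis = np.array([1.0, 0.8, 1.2, 1.05])
    config = _fake_configural(alphas, psis)
    res = align(config, method="fixed", reference="G1")
    assert np.abs(res.alpha - alphas).max() < 0.02
    assert np.abs(res.psi - psis).max() < 0.03
    spread_a = np.ptp([p.a for p in res.aligned], axis=0)
    spread_b = np.ptp([p.b for p in res.aligned], axis=0)
    assert spread_a.max() < 0.05 and spread_b.max() < 0.05
    # the optimum cannot be worse than the identity transformation
    a = np.array([p.a for p in config.params])
    b = np.array([p.b for p in config.params])
    iu = np.triu_indices(4, k=1)
    pw = np.ones(iu[0].size)
    assert (_total_loss(a, b, res.alpha, res.psi, pw, iu)
            <= _total_loss(a, b, np.zeros(4), np.ones(4), pw, iu) + 1e-9)


def test_group_relabeling_equivariance():
    alphas = np.array([0.0, -0.3, 0.4])
    psis = np.array([1.0, 1.1, 0.9])
    config = _fake_configural(alphas, psis)
    res = align(config, method="fixed", reference="G1")
    perm = [2, 0, 1]
    config_p = _fake_configural(alphas[perm], psis[perm])
    config_p.group_names = ["G3", "G1", "G2"]
    res_p = align(config_p, method="fixed", reference="G1")
    for g in ("G1", "G2", "G3"):
        i, ip = res.group_names.index(g), res_p.group_names.index(g)
        assert res.alpha[i] == pytest.approx(res_p.alpha[ip], abs=1e-3)


def test_alignment_recovery_on_fitted_data(aligned_nodif, nodif_scenario):
    _, truth = nodif_scenario
    names = list(truth["groups"])
    alpha_true = np.array([truth["groups"][g]["alpha"] for g in names])
    assert np.abs(aligned_nodif.alpha - alpha_true).max() <= 0.15
    order_est = np.argsort(aligned_nodif.alpha)
    order_true = np.argsort(alpha_true)
    assert np.array_equal(order_est, order_true)


def test_aligned_model_reproduces_configural_likelihood(aligned_nodif, configural_fit):
    assert aligned_loglik(aligned_nodif, configural_fit) == pytest.approx(
        configural_fit.loglik, abs=1e-8)


def test_free_method_identification(configural_fit):
    res = align(configural_fit, method="free")
    assert res.poorly_identified
    assert any("FIXED" in n for n in res.notes)


def test_flagging_specificity_and_summary(aligned_nodif):
    summary = flag_invariance(aligned_nodif)
    assert len(summary) == 40                # 8 slopes + 32 thresholds
    assert (summary.n_invariant == 8).mean() >= 0.9
    assert ((summary.pct_invariant >= 0) & (summary.pct_invariant <= 100)).all()


def test_flagging_sensitivity_noise_free():
    dif = [(4, 0, 2, 0.6), (4, 0, 5, 0.6)]  # item 5, threshold 1, groups 3 & 6
    config = _fake_configural(np.zeros(8), np.ones(8), dif=dif)
    res = align(config, method="fixed", reference="G1")
    summary = flag_invariance(res)
    row = summary[(summary["item"] == "item5") & (summary.parameter == "b1")].iloc[0]
    assert row.n_invariant == 6
    assert not {"G3", "G6"} & set(row.invariant_groups)


def test_single_group_trivially_invariant():
    # flagging with a single group marks every parameter invariant
    one = AlignmentResult(
        group_names=["G1"], method="fixed", reference="G1",
        alpha=np.zeros(1), psi=np.ones(1),
        aligned=[GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS)],
        configural=[GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS)],
        se_a=[np.full(8, 0.05)], se_b=[np.full((8, 4), 0.05)],
        n_per_group=np.array([100.0]), total_loss=0.0)
    summary = flag_invariance(one)
    assert (summary.n_invariant == 1).all()


def test_r2_pure_cases():
    # variation purely from (alpha, psi): R2 ~ 1 on every row that varies
    config = _fake_configural(np.array([0.0, -0.4, 0.3, 0.6]),
                              np.array([1.0, 0.8, 1.25, 1.1]))
    res = align(config, method="fixed", reference="G1")
    summary = invariance_r2(res)
    assert np.nanmin(summary.R2) > 0.95
    # variation purely from DIF at (alpha, psi) = (0, 1): R2 ~ 0
    dif = [(j, kk, g, off) for (j, kk, g, off) in
           [(0, 0, 1, 0.5), (0, 0, 2, -0.5), (0, 0, 3, 0.3)]]
    config2 = _fake_configural(np.zeros(4), np.ones(4), dif=dif)
    res2 = align(config2, method="fixed", reference="G1")
    summary2 = invariance_r2(res2)
    row = summary2[(summary2["item"] == "item1") & (summary2.parameter == "b1")]
    assert row.R2.iloc[0] < 0.3


def test_r2_monotone_in_dif_share():
    alphas, psis = np.array([0.0, -0.3, 0.3, 0.5]), np.ones(4)
    values = []
    for dif_size in (0.0, 0.4, 0.9):
        dif = [(0, 3, 1, dif_size), (0, 3, 2, 2 * dif_size)]   # last threshold
        config = _fake_configural(alphas, psis, dif=dif)
        res = align(config, method="fixed", reference="G1")
        summary = invariance_r2(res)
        row = summary[(summary["item"] == "item1") & (summary.parameter == "b4")]
        values.append(float(row.R2_raw.iloc[0]))
    assert values[0] > values[1] > values[2]


def test_mc_stability_validations(aligned_nodif):
    with pytest.raises(ValueError):
        alignment_stability_mc(aligned_nodif, reps=0)
    out = alignment_stability_mc(aligned_nodif, reps=2, seed=3,
                                 n_per_group=np.full(8, 300))
    assert out["n_completed"] + out["n_failed"] == 2
    assert out["coverage"].shape == (8,)
    assert out["mean_estimates"].shape == (8,)
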