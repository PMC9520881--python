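"""Differential test functioning and score comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclpipe.dtf import drf, expected_test_score, pairwise_dtf, sumscore_factor_comparison
from sclpipe.grm import GRMParams
from sclpipe.synthetic import DEFAULT_SLOPES, DEFAULT_THRESHOLDS

REF = GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS)


def test_expected_score_limits_and_oracle():
    assert expected_test_score(REF, 40.0) == pytest.approx(32.0, abs=1e-8)
    assert expected_test_score(REF, -40.0) == pytest.approx(0.0, abs=1e-8)
    p3 = GRMParams(a=DEFAULT_SLOPES[:3], b=DEFAULT_THRESHOLDS[:3])
    theta = 0.7
    brute = 0.0
    for j in range(3):
        pstar = np.concatenate([
            [1.0], 1 / (1 + np.exp(-p3.a[j] * (theta - p3.b[j]))), [0.0]])
        brute += (np.arange(5) * (pstar[:-1] - pstar[1:])).sum()
    assert expected_test_score(p3, theta) == pytest.approx(brute, abs=1e-12)


def test_drf_self_comparison_zero():
    r = drf(REF, REF)
    assert r.sdrf == 0.0 and r.udrf == 0.0
    assert np.allclose(r.difference, 0.0)


def test_uniform_shift_direction():
    foc = GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS + 0.5)
    r = drf(REF, foc)
    assert (r.difference > 0).all()          # reference scores higher everywhere
    assert r.sdrf > 0
    assert r.udrf == pytest.approx(r.sdrf, abs=1e-12)


def test_quadrature_matches_dense_trapezoid():
    from scipy.stats import norm

    foc = GRMParams(a=DEFAULT_SLOPES * 1.1, b=DEFAULT_THRESHOLDS + 0.3)
    r = drf(REF, foc)
    lat = np.linspace(-6, 6, 100_001)
    w = norm.pdf(lat)
    w /= np.trapezoid(w, lat)
    diff = expected_test_score(REF, lat) - expected_test_score(foc, lat)
    assert r.sdrf == pytest.approx(np.trapezoid(diff * w, lat), abs=1e-6)
    assert r.udrf == pytest.approx(np.trapezoid(np.abs(diff) * w, lat), abs=1e-6)


def test_lattice_refinement_convergence():
    foc = GRMParams(a=DEFAULT_SLOPES, b=DEFAULT_THRESHOLDS - 0.4)
    r1 = drf(REF, foc, lattice=np.linspace(-6, 6, 201))
    r2 = drf(REF, foc, lattice=np.linspace(-6, 6, 401))
    assert abs(r1.sdrf - r2.sdrf) < 1e-4
    assert abs(r1.udrf - r2.udrf) < 1e-4


def test_mismatched_items_error():
    with pytest.raises(ValueError, match="differ"):
        drf(REF, GRMParams(a=DEFAULT_SLOPES[:3], b=DEFAULT_THRESHOLDS[:3]))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 16))
def test_udrf_dominates_sdrf(seed):
    rng = np.random.default_rng(seed)
    a1 = rng.uniform(0.7, 2.5, 4)
    a2 = rng.uniform(0.7, 2.5, 4)
    b1 = np.sort(rng.normal(0.5, 1.0, (4, 4)), axis=1) + np.arange(4) * 1e-3
    b2 = np.sort(rng.normal(0.5, 1.0, (4, 4)), axis=1) + np.arange(4) * 1e-3
    r = drf(GRMParams(a=a1, b=b1), GRMParams(a=a2, b=b2),
            lattice=np.linspace(-6, 6, 101))
    assert r.udrf >= abs(r.sdrf) - 1e-12
    assert r.udrf >= 0


def test_pairwise_symmetries(aligned_nodif):
    out = pairwise_dtf(aligned_nodif)
    tab = out["table"]
    g = aligned_nodif.n_groups
    assert len(tab) == g * (g - 1) // 2
    # antisymmetry is exploited by construction; summary covers both orders
    assert out["summary"]["sDRF_mean"] == pytest.approx(0.0, abs=1e-12)
    assert out["summary"]["uDRF_min"] >= 0
    # invariant scenario: differential functioning stays small
    assert tab.uDRF.max() < 0.5


def test_drf_bootstrap_cis(aligned_nodif):
    i, j = 0, 1
    se = ((aligned_nodif.se_a[i], aligned_nodif.se_b[i]),
          (aligned_nodif.se_a[j], aligned_nodif.se_b[j]))
    r = drf(aligned_nodif.aligned[i], aligned_nodif.aligned[j],
            se=se, n_boot=99, seed=5)
    assert r.sdrf_ci[0] <= r.sdrf_ci[1]
    assert r.udrf_ci[0] <= r.udrf_ci[1]
    assert r.udrf_ci[1] >= 0
    assert r.difference_ci.shape == (r.theta.size, 2)


def test_injected_dif_pairs_have_largest_udrf():
    from sclpipe.alignment import AlignmentResult

    g = 4
    aligned, config = [], []
    for i in range(g):
        b = DEFAULT_THRESHOLDS.copy()
        if i == 3:
            b = b + 0.6                     # DIF-carrying group
        aligned.append(GRMParams(a=DEFAULT_SLOPES, b=b))
        config.append(GRMParams(a=DEFAULT_SLOPES, b=b))
    res = AlignmentResult(
        group_names=[f"G{i + 1}" for i in range(g)], method="fixed",
        reference="G1", alpha=np.zeros(g), psi=np.ones(g),
        aligned=aligned, configural=config,
        se_a=[np.full(8, 0.05)] * g, se_b=[np.full((8, 4), 0.05)] * g,
        n_per_group=np.full(g, 500.0), total_loss=0.0)
    out = pairwise_dtf(res)
    tab = out["table"]
    with_dif = tab[(tab.ref == "G4") | (tab.focal == "G4")]
    without = tab[(tab.ref != "G4") & (tab.focal != "G4")]
    assert with_dif.uDRF.min() > without.uDRF.max()


def test_sumscore_factor_comparison(aligned_nodif, nodif_scenario):
    data, _ = nodif_scenario
    out = sumscore_factor_comparison(aligned_nodif, data)
    tab = out["per_group"]
    assert len(tab) == 8
    assert (tab.r > 0.9).all()               # sum and factor scores track closely
    assert out["cross_group_mean_correlation"] > 0.95
    assert (tab.r <= 1.0).all() and (tab.slope > 0).all()
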