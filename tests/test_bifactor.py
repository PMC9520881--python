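"""Bifactor GRM and the unidimensional-enough comparison toolkit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclpipe.bifactor import (
    BifactorParams,
    average_relative_bias,
    bifactor_indices,
    compare_models,
    fit_bifactor_grm,
    marginal_slopes,
)
from sclpipe.synthetic import DEFAULT_THRESHOLDS


def _params(a_g, a_s, cluster=None):
    a_g = np.asarray(a_g, float)
    j = a_g.size
    return BifactorParams(
        a_g=a_g, a_s=np.asarray(a_s, float),
        cluster=np.asarray(cluster if cluster is not None else [0] * j),
        b=DEFAULT_THRESHOLDS[:j])


def test_marginal_slope_closed_form():
    p = _params([1.702], [1.702])
    # lambda_g = 1/sqrt(3) -> marginal slope 1.702/sqrt(2)
    assert marginal_slopes(p)[0] == pytest.approx(1.702 / np.sqrt(2), abs=1e-10)


def test_marginal_slope_reduction_and_monotonicity():
    p0 = _params([1.3, 2.0], [0.0, 0.0])
    assert np.allclose(marginal_slopes(p0), [1.3, 2.0])     # exact when a_s = 0
    grid = [marginal_slopes(_params([1.5], [v]))[0] for v in (0.0, 0.5, 1.0, 2.0)]
    assert all(x > y for x, y in zip(grid, grid[1:]))


def test_average_relative_bias_arithmetic():
    assert average_relative_bias(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
    assert average_relative_bias(1.2 * np.ones(4), np.ones(4)) == pytest.approx(20.0)
    with pytest.warns(UserWarning):
        out = average_relative_bias(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
    assert out == 0.0
    with pytest.raises(ValueError):
        average_relative_bias(np.ones(3), np.ones(4))


@pytest.mark.parametrize("split,expected", [
    ((5, 3), 15 / 28), ((4, 4), 16 / 28), ((6, 2), 12 / 28)])
def test_puc_pair_counts(split, expected):
    cluster = np.array([0] * split[0] + [1] * split[1])
    p = _params(np.full(8, 1.5), np.full(8, 0.8), cluster)
    assert bifactor_indices(p).puc == pytest.approx(expected, abs=1e-12)


def test_ecv_identities():
    cluster = np.array([0, 0, 0, 0, 0, 1, 1, 1])
    p = _params(np.full(8, 1.5), np.array([0.4] * 5 + [1.0] * 3), cluster)
    idx = bifactor_indices(p)
    assert idx.ecv_g + sum(idx.ecv_s.values()) == pytest.approx(1.0, abs=1e-8)
    assert 0 <= idx.h_general <= 1 and 0 <= idx.fd_general <= 1
    pure = _params(np.full(8, 1.5), np.zeros(8), cluster)
    assert bifactor_indices(pure).ecv_g == pytest.approx(1.0)


def test_specific_slope_recovery(bifactor_fit, bifactor_data):
    mask = bifactor_data["mask"]
    in_cluster = mask == 1
    rmse = np.sqrt(np.mean(
        (bifactor_fit.params.a_s[in_cluster] - bifactor_data["a_s"][in_cluster]) ** 2))
    assert rmse < 0.2
    assert np.all(bifactor_fit.params.a_s[~in_cluster] == 0.0)
    rmse_g = np.sqrt(np.mean((bifactor_fit.params.a_g - bifactor_data["a_g"]) ** 2))
    assert rmse_g < 0.2


def test_reduction_on_unidimensional_data(null_bifactor_pair):
    uni, bif = null_bifactor_pair["uni"], null_bifactor_pair["bif"]
    assert bif.loglik >= uni.loglik          # nested models
    rep = compare_models(uni, bif)
    assert rep.score_correlation > 0.99
    assert abs(rep.delta_reliability) < 0.05
    # the general dimension is unchanged: marginal slopes near the truth
    a_marg = marginal_slopes(bif.params)
    assert np.abs(a_marg - null_bifactor_pair["a_g"]).max() < 0.25
    assert rep.average_relative_bias < 10.0


def test_comparison_report_shapes(bifactor_fit, bifactor_data):
    from sclpipe.grm import fit_grm

    uni = fit_grm(bifactor_data["responses"], compute_se=False)
    rep = compare_models(uni, bifactor_fit)
    assert rep.theta_lattice.shape == rep.tcc_uni.shape == rep.tcc_bifactor.shape
    assert (rep.tif_bifactor >= 0).all()
    assert np.all(np.diff(rep.tcc_bifactor) > 0)
    assert -1 <= rep.score_correlation <= 1
    assert rep.average_relative_bias >= 0


def test_structure_validation(bifactor_data):
    with pytest.raises(ValueError, match="cluster"):
        fit_bifactor_grm(bifactor_data["responses"], np.array([0, 1]))
    with pytest.raises(ValueError, match="increasing"):
        BifactorParams(a_g=[1.0], a_s=[0.5], cluster=[0], b=[[1.0, 0.0, 2.0, 3.0]])


def test_singleton_cluster_fixed(bifactor_data):
    mask = np.array([0, 0, 0, 0, 0, 0, 0, 1])      # one-item specific factor
    fit = fit_bifactor_grm(bifactor_data["responses"][:600], mask, max_cycles=30)
    assert fit.params.a_s[7] == 0.0
    assert any("one item" in n for n in fit.notes)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.floats(0.5, 3.0), st.floats(0.0, 2.5))
def test_loading_conversion_is_proper(a_g, a_s):
    p = _params([a_g], [a_s])
    lam_g, lam_s, _ = p.standardized_loadings()
    assert lam_g[0] ** 2 + lam_s[0] ** 2 < 1.0
    m = marginal_slopes(p)[0]
    assert 0 < m <= a_g + 1e-12
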