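"""Generator correctness: saturation, calibration, determinism, DIF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclpipe.grm import GRMParams, category_probabilities
from sclpipe.synthetic import (
    DEFAULT_CLUSTERS,
    DEFAULT_SLOPES,
    DEFAULT_THRESHOLDS,
    DIFEntry,
    GroupSpec,
    SimulationSpec,
    make_hbsc_like_defaults,
    make_multigroup_scenario,
    simulate_bifactor,
    simulate_grm,
)


def test_saturated_thresholds():
    b_low = np.full((2, 4), -10.0) + np.arange(4) * 0.1
    x = simulate_grm((np.array([1.0, 2.0]), b_low), 100, seed=0)
    assert (x == 4).all()
    b_high = np.full((2, 4), 10.0) + np.arange(4) * 0.1
    x = simulate_grm((np.array([1.0, 2.0]), b_high), 100, seed=0)
    assert (x == 0).all()


def test_cumulative_probability_at_threshold():
    # P(X >= 2 | theta = b_2) = 0.5 by the logistic midpoint
    a, b = np.array([1.5]), np.array([[-1.0, 0.0, 1.0, 2.0]])
    x = simulate_grm((a, b), 50_000, theta_dist=(0.0, 1e-12), seed=1)
    assert np.mean(x >= 2) == pytest.approx(0.5, abs=0.01)


def test_seed_determinism_and_child_streams():
    params = (DEFAULT_SLOPES, DEFAULT_THRESHOLDS)
    assert np.array_equal(simulate_grm(params, 200, seed=7),
                          simulate_grm(params, 200, seed=7))
    gs = [GroupSpec(name=f"G{i}", n=100) for i in range(3)]
    d3, _ = make_multigroup_scenario(SimulationSpec(groups=gs, seed=9))
    gs4 = gs + [GroupSpec(name="G3", n=100)]
    d4, _ = make_multigroup_scenario(SimulationSpec(groups=gs4, seed=9))
    # adding a group never perturbs the existing groups' draws
    assert np.array_equal(d3.responses, d4.responses[:300])


def test_unordered_thresholds_error():
    with pytest.raises(ValueError, match="increasing"):
        simulate_grm((np.array([1.0]), np.array([[0.0, -1.0, 1.0, 2.0]])), 10)


def test_bifactor_reduces_to_grm_in_distribution():
    a = DEFAULT_SLOPES
    xb = simulate_bifactor((a, np.zeros(8), DEFAULT_CLUSTERS, DEFAULT_THRESHOLDS),
                           50_000, seed=3)
    xg = simulate_grm((a, DEFAULT_THRESHOLDS), 50_000, seed=4)
    assert np.allclose(xb.mean(axis=0), xg.mean(axis=0), atol=0.03)
    assert np.allclose(np.corrcoef(xb.T), np.corrcoef(xg.T), atol=0.03)
    assert np.array_equal(
        simulate_bifactor((a, np.ones(8), DEFAULT_CLUSTERS, DEFAULT_THRESHOLDS), 50, seed=5),
        simulate_bifactor((a, np.ones(8), DEFAULT_CLUSTERS, DEFAULT_THRESHOLDS), 50, seed=5))


def test_bifactor_structure_validation():
    with pytest.raises(ValueError, match="number of items"):
        simulate_bifactor((np.ones(3), np.ones(2), np.array([0, 0, 1]),
                           np.tile([-1.0, 0.0, 1.0, 2.0], (3, 1))), 10)


def test_dif_bookkeeping_exact():
    gs = [GroupSpec(name=f"G{i}", n=50) for i in range(4)]
    spec = SimulationSpec(groups=gs,
                          dif=[DIFEntry(item=5, parameter="b1", group="G2", offset=0.5)],
                          seed=1)
    _, truth = make_multigroup_scenario(spec)
    delta = truth["groups"]["G2"]["thresholds"] - truth["groups"]["G0"]["thresholds"]
    assert delta[5, 0] == pytest.approx(0.5)
    assert np.abs(np.delete(delta.ravel(), 5 * 4)).max() == 0.0
    assert truth["invariant"]["b"][5][0] is False
    assert truth["invariant"]["a"] == [True] * 8


def test_dif_breaking_order_errors():
    gs = [GroupSpec(name="A", n=10), GroupSpec(name="B", n=10)]
    spec = SimulationSpec(groups=gs,
                          dif=[DIFEntry(item=0, parameter="b1", group="B", offset=5.0)],
                          seed=0)
    with pytest.raises(ValueError, match="threshold order"):
        make_multigroup_scenario(spec)


def test_scenario_row_count():
    gs = [GroupSpec(name=f"G{i}", n=500) for i in range(32)]
    data, _ = make_multigroup_scenario(SimulationSpec(groups=gs, seed=0))
    assert data.n_persons == 16_000


def test_defaults_pass_invariants_and_skewness():
    spec = make_hbsc_like_defaults(seed=0)
    assert spec.n_items == 8 and spec.n_categories == 5
    a0, b0, _ = spec.resolved_group_params(spec.groups[0])
    assert np.all((a0 >= 0.7) & (a0 <= 3.1))
    assert set(np.argsort(a0)[-3:]) == {3, 4, 5}          # items 4-6 steepest
    x = simulate_grm((a0, b0), 10_000, seed=2)
    from scipy.stats import skew
    sk = skew(x, axis=0)
    assert (sk > 0).sum() >= 6                            # right-skewed items


def test_default_polychoric_range():
    from sclpipe.descriptives import polychoric_matrix

    spec = make_hbsc_like_defaults(n_groups=2, n_per_group=2000, seed=4)
    data, _ = make_multigroup_scenario(spec)
    poly = polychoric_matrix(data.responses)
    off = poly.corr[np.triu_indices(8, k=1)]
    assert off.min() > 0.15 and off.max() < 0.88


def test_category_proportions_converge_to_model():
    a, b = DEFAULT_SLOPES, DEFAULT_THRESHOLDS
    x = simulate_grm((a, b), 100_000, seed=6)
    theta = np.linspace(-6, 6, 201)
    from scipy.stats import norm

    w = norm.pdf(theta)
    w /= w.sum()
    probs = category_probabilities(GRMParams(a=a, b=b), theta)  # (T, J, K)
    marginal = np.einsum("tjk,t->jk", probs, w)
    empirical = np.stack([(x == k).mean(axis=0) for k in range(5)], axis=1)
    assert np.abs(marginal - empirical).max() < 0.01


def test_yaml_roundtrip():
    spec = make_hbsc_like_defaults(n_groups=3, n_per_group=100, seed=2)
    text = spec.to_yaml()
    back = SimulationSpec.from_yaml(text)
    assert back.n_items == spec.n_items
    assert back.groups[1].n == spec.groups[1].n
    assert np.allclose(back.groups[2].thresholds, spec.groups[2].thresholds)
    assert back.dif == spec.dif


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.floats(-3, 3), st.floats(0.2, 3.0), st.integers(0, 2 ** 16))
def test_responses_in_range(mean, var, seed):
    x = simulate_grm((DEFAULT_SLOPES[:3], DEFAULT_THRESHOLDS[:3]), 50,
                     theta_dist=(mean, var), seed=seed)
    assert x.shape == (50, 3)
    assert x.min() >= 0 and x.max() <= 4
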