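"""Shared fixtures: simulated datasets and fitted models reused across tests.

Everything is generated programmatically with fixed seeds; the expensive
model fits are session-scoped so each is computed once.
"""

import numpy as np
import pytest

from sclpipe.grm import fit_grm
from sclpipe.invariance import fit_multigroup
from sclpipe.synthetic import (
    DEFAULT_SLOPES,
    DEFAULT_THRESHOLDS,
    GroupSpec,
    SimulationSpec,
    make_hbsc_like_defaults,
    make_multigroup_scenario,
    simulate_bifactor,
    simulate_grm,
)

TRUE_A = DEFAULT_SLOPES
TRUE_B = DEFAULT_THRESHOLDS


@pytest.fixture(scope="session")
def uni3000():
    """n=3000 unidimensional sample from the default item parameters."""
    x = simulate_grm((TRUE_A, TRUE_B), 3000, seed=42)
    return {"responses": x, "a": TRUE_A, "b": TRUE_B}


@pytest.fixture(scope="session")
def grm_fit_3000(uni3000):
    return fit_grm(uni3000["responses"])


@pytest.fixture(scope="session")
def nodif_scenario():
    """8 invariant groups x 1000, latent means/variances spread."""
    spec = make_hbsc_like_defaults(n_groups=8, n_per_group=1000,
                                   bifactor=False, with_dif=False, seed=0)
    return make_multigroup_scenario(spec)


@pytest.fixture(scope="session")
def configural_fit(nodif_scenario):
    data, _ = nodif_scenario
    return fit_multigroup(data, "configural")


@pytest.fixture(scope="session")
def scalar_fit(nodif_scenario):
    data, _ = nodif_scenario
    return fit_multigroup(data, "scalar", max_cycles=1000)


@pytest.fixture(scope="session")
def metric_scenario():
    """8 groups x 1000 with latent means 0 (metric-model identification)."""
    groups = [GroupSpec(name=f"G{i + 1}", n=1000, alpha=0.0,
                        psi=float(p), slopes=TRUE_A.copy(),
                        thresholds=TRUE_B.copy())
              for i, p in enumerate(np.linspace(1.0, 1.3, 8))]
    groups[0].psi = 1.0
    spec = SimulationSpec(groups=groups, seed=5)
    return make_multigroup_scenario(spec)


@pytest.fixture(scope="session")
def metric_fit(metric_scenario):
    data, _ = metric_scenario
    return fit_multigroup(data, "metric", max_cycles=1000)


@pytest.fixture(scope="session")
def aligned_nodif(configural_fit):
    from sclpipe.alignment import align

    return align(configural_fit, method="fixed",
                 reference=configural_fit.group_names[0], seed=1)


BIF_MASK = np.array([-1, -1, -1, 1, 1, 1, -1, -1])


@pytest.fixture(scope="session")
def bifactor_data():
    """Identified bifactor truth: one specific cluster on items 4-6."""
    a_g = np.full(8, 1.5)
    a_s = np.where(BIF_MASK == 1, 1.0, 0.0)
    x = simulate_bifactor((a_g, a_s, BIF_MASK, TRUE_B), 3000, seed=11)
    return {"responses": x, "a_g": a_g, "a_s": a_s, "mask": BIF_MASK}


@pytest.fixture(scope="session")
def bifactor_fit(bifactor_data):
    from sclpipe.bifactor import fit_bifactor_grm

    return fit_bifactor_grm(bifactor_data["responses"], bifactor_data["mask"])


@pytest.fixture(scope="session")
def null_bifactor_pair():
    """Unidimensional data fitted both ways (reduction checks)."""
    from sclpipe.bifactor import fit_bifactor_grm

    a_g = np.full(8, 1.5)
    x = simulate_grm((a_g, TRUE_B), 3000, seed=12)
    return {
        "a_g": a_g,
        "uni": fit_grm(x, compute_se=False),
        "bif": fit_bifactor_grm(x, BIF_MASK),
    }
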