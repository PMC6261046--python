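import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from corticodev import (
    aggregate_connectome,
    analyze_instance,
    get_layout,
    params_for_layout,
    run_instance,
    structural_measures,
)

#: Small total_steps / low density used by unit tests that only need the
#: mechanics, not the calibrated study conditions.
FAST_STEPS = 60


@pytest.fixture(scope="session")
def sim_1d():
    """One calibrated realistic 1D instance, shared across tests."""
    cfg = get_layout("1D-1row-2or")
    return run_instance(cfg, params_for_layout(cfg), seed=101)


@pytest.fixture(scope="session")
def connectome_1d(sim_1d):
    return aggregate_connectome(
        sim_1d.synapses, sim_1d.neuron_area, sim_1d.sheet.n_areas
    )


@pytest.fixture(scope="session")
def measures_1d(sim_1d):
    return structural_measures(sim_1d.sheet)


@pytest.fixture(scope="session")
def report_1d(connectome_1d, measures_1d):
    return analyze_instance(connectome_1d, measures_1d)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
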