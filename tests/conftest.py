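import numpy as np
import pytest

from pdxsig import synthetic
from pdxsig.config import SelectionConfig, SimulationConfig


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic study: no growth noise, no expression/Ct noise."""
    return SimulationConfig(
        seed=11,
        volume_noise_cv=0.0,
        model_effect_sd=0.0,
        residual_sd=0.0,
        ct_replicate_sd=0.0,
    )


@pytest.fixture(scope="session")
def study(sim_config):
    return synthetic.simulate_growth_study(sim_config)


@pytest.fixture(scope="session")
def ct_sim(sim_config):
    return synthetic.simulate_ct_table(sim_config)


@pytest.fixture(scope="session")
def expression_matrix(ct_sim):
    from pdxsig import qpcr

    return qpcr.build_expression_matrix(
        ct_sim.table,
        sample_model=ct_sim.sample_model,
        model_response=ct_sim.model_response,
        reference_samples=ct_sim.reference_samples,
    )


@pytest.fixture(scope="session")
def selection_config():
    return SelectionConfig(seed=7)
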