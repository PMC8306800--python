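import numpy as np
import pytest

import mirlink as ml


@pytest.fixture(scope="session")
def planted_config():
    """Planted protective miRNA: low expression in advanced disease."""
    return ml.SimulationConfig(
        seed=7, n_mirna=10, planted_mirna_effects={"mir-001": -1.0}
    )


@pytest.fixture(scope="session")
def planted_run(planted_config):
    registry = ml.simulate_registry(planted_config)
    expr, clinical = ml.simulate_expression_cohort(planted_config)
    return registry, expr, clinical


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
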