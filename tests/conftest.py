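import logging

import numpy as np
import pytest

from conngrad import SimulationConfig, simulate_cohort, contrast_pipeline

logging.getLogger("conngrad").setLevel(logging.ERROR)


def small_config(**kw):
    """Desk-scale cohort config used across tests (fast but fully featured)."""
    base = dict(n_cortical=60, n_patients=12, n_controls=12, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted effects at reduced size."""
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """Same generator with every group effect switched off."""
    return simulate_cohort(
        small_config(seed=12, effect_expand=0.0, effect_contract=0.0, subcortical_degree_effect=1.0)
    )


@pytest.fixture(scope="session")
def planted_pipeline(planted_cohort):
    return contrast_pipeline(planted_cohort, n_perm=200, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
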