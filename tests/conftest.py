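import numpy as np
import pytest

from metabodiscrim import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort used by unit tests: full sample size, few features."""
    return GeneratorConfig(
        n_eca=12,
        n_eca_known=4,
        n_gctof=20,
        n_gctof_known=8,
        n_drug_confounded=4,
        n_apoe_linked=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250921)
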