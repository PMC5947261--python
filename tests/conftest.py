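import numpy as np
import pytest

from isoniche.synthetic import SyntheticConfig, generate_isotope_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20180301)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One default-configuration synthetic dataset, shared across tests.

    Triggers the (cached) within-covariance calibration once per session.
    """
    return generate_isotope_dataset(default_config)
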