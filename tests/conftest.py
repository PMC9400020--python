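import numpy as np
import pytest

from nichedrift import MetacommunitySample, MsnConfig, simulate_neutral_metacommunity


@pytest.fixture(scope="session")
def fast_config():
    """Small Gibbs schedule for unit tests (100 retained draws)."""
    return MsnConfig(n_iterations=600, burn_in=300, thin=3, seed=123)


@pytest.fixture(scope="session")
def neutral_sample():
    """Mid-size neutral metacommunity with known truth (theta=30, I=20)."""
    rng = np.random.default_rng(2024)
    return simulate_neutral_metacommunity(
        30.0, np.full(5, 20.0), np.full(5, 800), rng
    )


@pytest.fixture
def tiny_sample():
    return MetacommunitySample(
        ["a", "b"], np.array([[3, 1, 0], [0, 2, 2]])
    )
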