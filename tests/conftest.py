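import numpy as np
import pytest

from stochhh import HHParameters


@pytest.fixture(scope="session")
def params() -> HHParameters:
    """Standard squid-axon parameters at the reference area 400 um^2."""
    return HHParameters()


@pytest.fixture(scope="session")
def small_params() -> HHParameters:
    """A tiny patch (few channels) for fast exact Markov-chain runs."""
    return HHParameters(area=5.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
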