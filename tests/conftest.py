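import pytest

from tcellnet.model import build_model
from tcellnet.network import parse_rules


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def core(model):
    return model.core


@pytest.fixture(scope="session")
def full(model):
    return model.full


@pytest.fixture()
def toy_cycle():
    """Two-node negative-free swap network: period-2 cycle plus two fixed points."""
    return parse_rules("A <- B\nB <- A")


@pytest.fixture()
def toy_latch():
    """One-node self-loop: both states are fixed points."""
    return parse_rules("A <- A")
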