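import numpy as np
import pytest

from perfunet.parameters import load_preset


@pytest.fixture(scope="session")
def panelA():
    tissue, transport, medium = load_preset("panelA")
    return tissue, transport, medium


@pytest.fixture(scope="session")
def panelD():
    tissue, transport, medium = load_preset("panelD")
    return tissue, transport, medium


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
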