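import numpy as np
import pytest

from selindex import huaxi_parameters


@pytest.fixture(scope="session")
def huaxi():
    """The built-in Huaxi cattle parameter set (WEI-12, DMY)."""
    return huaxi_parameters()


@pytest.fixture(scope="session")
def huaxi_weights():
    """Economic weights of the baseline condition C1."""
    return np.array([0.5, 1.0])
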