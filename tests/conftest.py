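import numpy as np
import pytest

import entsim


@pytest.fixture(scope="session", autouse=True)
def warm_kernel():
    """Compile the integration kernel once so test timings are stable."""
    n = entsim.build_neuron()
    entsim.integrate(n, 5.0)


@pytest.fixture(scope="session")
def channels():
    return entsim.default_channels()


@pytest.fixture(scope="session")
def channel_map(channels):
    return {c.name: c for c in channels}


@pytest.fixture(scope="session")
def vgrid():
    return np.arange(-120.0, 60.0 + 0.5, 0.5)
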