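import numpy as np
import pytest

from spheroquant import physics


@pytest.fixture
def water():
    return physics.FluidMedium(density=1000.0, viscosity=1.0e-3)


@pytest.fixture
def channel():
    return physics.ChannelGeometry(radius=5e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
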