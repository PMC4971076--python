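import numpy as np
import pytest

from spikeloop import TimeGrid, make_fixture


@pytest.fixture
def ms_grid():
    """One second at 1 ms resolution — the standard neural grid."""
    return TimeGrid(0.0, 1.0, 1e-3)


@pytest.fixture
def sine3(ms_grid):
    """Three-channel 1 Hz sinusoid fixture."""
    return make_fixture("sine", ms_grid, channels=3, freq=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
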