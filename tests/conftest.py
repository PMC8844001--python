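import numpy as np
import pytest

from stressdfc import RoiTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """20 volumes x 4 ROIs around a 100-unit baseline."""
    return RoiTimeSeries(100.0 + rng.normal(0, 1, size=(20, 4)), tr_seconds=2.0)
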