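import numpy as np
import pytest

from spikelink import SpikeTrainSet


def poisson_train(rate, duration, rng, fs=10_000.0):
    """Homogeneous Poisson spike times snapped to the sampling grid."""
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0, duration, size=n))
    idx = np.unique(np.round(t * fs).astype(np.int64))
    return idx / fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_set():
    """Channel b is a copy of channel a shifted by +5 ms."""
    rng = np.random.default_rng(7)
    a = poisson_train(8.0, 60.0, rng)
    b = np.round((a + 0.005) * 10_000) / 10_000
    b = b[b <= 60.0]
    return SpikeTrainSet({"a": a, "b": b}, 10_000.0, 60.0)
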