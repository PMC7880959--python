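import numpy as np
import pytest

from gazevents import GazeSeries, VelocitySeries


def make_series(x, y=None, fs=1000.0, px2deg=0.01) -> GazeSeries:
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    return GazeSeries(x, np.asarray(y, dtype=float), fs, px2deg)


def make_velocity(v, fs=1000.0) -> VelocitySeries:
    return VelocitySeries(np.asarray(v, dtype=float), fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
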