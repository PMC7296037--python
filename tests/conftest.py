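import numpy as np
import pytest

from gammaflick import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_signal(rng):
    return Signal(rng.standard_normal(16384), fs=1000.0)


def make_sine(freq_hz: float, fs: float = 1000.0, duration_s: float = 2.0,
              amp: float = 1.0, phase: float = 0.0) -> Signal:
    t = np.arange(int(round(duration_s * fs))) / fs
    return Signal(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs)


@pytest.fixture
def sine_40hz():
    return make_sine(40.0, fs=1000.0, duration_s=2.0)
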