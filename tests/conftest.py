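import numpy as np
import pytest

from fetalhrv.beats import BeatSeries, UniformSeries

RATE = 8.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tone_window(freq, amp=10.0, n=512, rate=RATE, base=400.0, phase=0.0):
    t = np.arange(n) / rate
    return base + amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def tone():
    return tone_window


def make_beats(rr_ms, start=0.0):
    return BeatSeries.from_rr(np.asarray(rr_ms, dtype=float), start_time=start)


@pytest.fixture
def beats_factory():
    return make_beats


def uniform_from(values, rate=RATE, start=0.0):
    return UniformSeries(start_time=start, rate=rate, values=np.asarray(values, float))


@pytest.fixture
def uniform_factory():
    return uniform_from
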