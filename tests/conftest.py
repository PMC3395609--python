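import numpy as np
import pytest

from impfa import TimeSeries


def tone(freq, duration_s=300.0, rate=50.0, amp=1.0, phase_deg=0.0):
    t = np.arange(int(round(duration_s * rate))) / rate
    return amp * np.sin(2 * np.pi * freq * t + np.radians(phase_deg))


@pytest.fixture
def two_tone_ts():
    """1 Hz + 0.05 Hz unit sines, 300 s at 50 Hz."""
    return TimeSeries(tone(1.0) + tone(0.05), rate=50.0, label="two_tone")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
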