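import numpy as np
import pytest

from blinkdet import DetectionSettings, SampleSeries, SimConfig, simulate_recording


def make_series(values, fs=600.0, valid=None, channel="eo", eye="left"):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    t = np.arange(len(values)) / fs
    return SampleSeries(t, values, np.asarray(valid, dtype=bool), fs, channel, eye)


@pytest.fixture
def settings():
    return DetectionSettings()


@pytest.fixture(scope="session")
def default_sim():
    """One simulated 60 s prompted-blink trial (shared, read-only)."""
    return simulate_recording(SimConfig(seed=1))
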