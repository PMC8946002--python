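import numpy as np
import pytest

from plinet.types import AnalysisConfig, DEFAULT_BANDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def alpha1():
    return DEFAULT_BANDS[1]


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def small_recording(rng):
    """A 4-channel, 10-s noise recording at 256 Hz."""
    from plinet.types import EEGRecording

    data = rng.normal(0, 10, size=(4, 2560))
    return EEGRecording(["Fp1", "Fp2", "O1", "O2"], 256.0, data)
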