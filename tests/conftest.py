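import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from speechscreen.synth import VoiceSpec, synthesize_voice

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="features constant within gender")


@pytest.fixture(scope="session")
def clean_voice_150():
    """Unperturbed 150 Hz voice plus its ground-truth pulse times."""
    audio, times, amps = synthesize_voice(VoiceSpec(f0_hz=150.0, duration_s=2.0, seed=11))
    return audio, times, amps


@pytest.fixture(scope="session")
def clean_voice_100():
    """Unperturbed 100 Hz voice (period = integer number of samples at 16 kHz)."""
    audio, times, amps = synthesize_voice(VoiceSpec(f0_hz=100.0, duration_s=2.0, seed=5))
    return audio, times, amps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
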