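import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcgseg import PCGRecording, SynthConfig, generate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_recording():
    """10 s, 60 bpm, jitter-free synthetic recording with its ground truth."""
    return generate(SynthConfig(duration_s=10.0, bpm=60.0, seed=1))


@pytest.fixture(scope="session")
def jittered_recording():
    """10 s, 100 bpm recording with 5% cycle jitter on the diastole."""
    return generate(SynthConfig(duration_s=10.0, bpm=100.0, cycle_jitter=0.05, seed=2))


@pytest.fixture()
def tone_4k():
    """2 s pure 200 Hz tone at 4 kHz (inside the heart sound passband)."""
    t = np.arange(8000) / 4000.0
    return PCGRecording(np.sin(2 * np.pi * 200 * t), 4000.0, "tone200")
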