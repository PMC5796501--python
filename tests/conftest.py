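import numpy as np
import pytest

from sdbsound.io_audio import AudioRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_tone(freq: float, duration_s: float = 5.0, rate: int = 8000, amplitude: float = 0.5,
              phase: float = 0.1) -> np.ndarray:
    t = np.arange(round(duration_s * rate)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture
def tone_window():
    """5 s, 1 kHz tone at 8 kHz."""
    return make_tone(1000.0)


@pytest.fixture
def noise_recording(rng):
    return AudioRecording(samples=0.1 * rng.standard_normal(8000 * 10), rate=8000,
                          subject_id="noise")
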