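import numpy as np
import pytest

from vicfreeze.audio_io import AudioTrack
from vicfreeze.synthetic_data import AudioSimSpec, simulate_audio

FS = 96_000


@pytest.fixture
def tone_track():
    """1-second full-scale-safe 22 kHz sine at 96 kHz."""
    t = np.arange(FS) / FS
    return AudioTrack(0.5 * np.sin(2 * np.pi * 22_000 * t), FS)


@pytest.fixture(scope="session")
def small_recording():
    """30-s synthetic cage recording with 8 ground-truth calls at 20 dB SNR."""
    spec = AudioSimSpec(duration=30.0, n_calls=8, snr_db=20.0)
    return simulate_audio(spec, seed=101)


@pytest.fixture(scope="session")
def noise_recording():
    """20-s call-free cage recording (background + clatter transients only)."""
    spec = AudioSimSpec(duration=20.0, n_calls=0, transient_rate=6.0)
    return simulate_audio(spec, seed=102)[0]
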