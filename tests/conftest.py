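import numpy as np
import pytest

from gammaforge import synth
from gammaforge.trace import Trace


@pytest.fixture
def clean_sinusoid_60s():
    """Noise-free 30 Hz, 10 µV sinusoid, 60 s at 10 kHz (variance 50 µV²)."""
    trace, _ = synth.gen_lfp(synth.OscillationSpec(
        frequency=30.0, amplitude=10.0, noise_sd=0.0, duration=60.0,
        sampling_rate=10_000.0, seed=0))
    return trace


@pytest.fixture
def modulated_gamma():
    """Amplitude-modulated 30 Hz oscillation with a known envelope.

    The envelope sweeps 2–10 µV at 0.7 Hz so that a broad range of cycle
    amplitudes (including the 30–70 % selection window) is populated.
    """
    fs = 10_000.0
    t = np.arange(0, 4.0, 1.0 / fs)
    envelope = 6.0 + 4.0 * np.sin(2 * np.pi * 0.7 * t)
    x = envelope * np.sin(2 * np.pi * 30.0 * t)
    return Trace(x, fs), envelope
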