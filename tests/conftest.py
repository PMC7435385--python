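import numpy as np
import pytest

from ppghr import SampledSignal, SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_recording():
    """Five minutes of clean synthetic PPG at a constant 80 bpm."""
    config = SyntheticConfig(seed=11, duration_s=300.0)
    signal, beats = generate(config)
    return config, signal, beats


def sine(freq_hz: float, duration_s: float = 60.0, fs: float = 128.0, amp: float = 1.0) -> SampledSignal:
    t = np.arange(int(round(duration_s * fs))) / fs
    return SampledSignal(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)
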