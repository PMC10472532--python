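import numpy as np
import pytest

from oxicam.signals import SkinColorSignal, SpO2Trace
from oxicam.synthetic import (
    BreathProtocolParams,
    OptoModelParams,
    generate_skin_signal,
    render_synthetic_frames,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def constant_spo2_trace():
    return SpO2Trace(times=np.arange(60.0), values=np.full(60, 95.0), rate=1.0)


@pytest.fixture(scope="session")
def noiseless_sine_opto():
    return OptoModelParams(noise_sd=0.0, waveform="sine", heart_rate=72.0)


@pytest.fixture(scope="session")
def noiseless_sine_signal(constant_spo2_trace, noiseless_sine_opto):
    return generate_skin_signal(constant_spo2_trace, noiseless_sine_opto)


@pytest.fixture(scope="session")
def rendered_sequence(noiseless_sine_signal):
    """90 rendered frames with pixel noise sigma=2 plus ground truth."""
    signal = SkinColorSignal(noiseless_sine_signal.values[:, :90], fps=30.0)
    frames, mask = render_synthetic_frames(signal, pixel_noise_sd=2.0, seed=77)
    return frames, mask, signal


@pytest.fixture(scope="session")
def default_protocol():
    return BreathProtocolParams(seed=2024)
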