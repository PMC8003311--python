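import numpy as np
import pytest

from quietscape.audio_io import AudioClip
from quietscape.spectral import Spectrogram


def make_spectrogram(values: np.ndarray, frame_step_s: float = 1.0,
                     nyquist_hz: float | None = None) -> Spectrogram:
    """Wrap a raw (T, F) matrix as a Spectrogram for direct index math."""
    values = np.asarray(values, dtype=float)
    t, f = values.shape
    top = nyquist_hz if nyquist_hz is not None else 1000.0 * (f - 1)
    freqs = np.linspace(0.0, top, f)
    return Spectrogram(
        values=values,
        frame_times_s=np.arange(t) * frame_step_s,
        bin_freqs_hz=freqs,
        frame_step_s=frame_step_s,
        window_len=2 * (f - 1),
    )


def sine_clip(freq_hz: float, duration_s: float = 1.0, sample_rate: int = 22050,
              amplitude: float = 0.8) -> AudioClip:
    t = np.arange(int(duration_s * sample_rate)) / sample_rate
    return AudioClip(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                     sample_rate=sample_rate)


@pytest.fixture
def tone_4khz() -> AudioClip:
    return sine_clip(4000.0)


@pytest.fixture
def silence() -> AudioClip:
    return AudioClip(samples=np.zeros(22050), sample_rate=22050)
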