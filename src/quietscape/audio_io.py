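"""WAV reading/writing and waveform conditioning.

All analysis operates on a canonical representation: full-scale-normalized
float64 samples in [-1, 1] at a known sample rate. Integer PCM is rescaled
by the type's maximum magnitude (so -32768 in 16-bit maps to -1.0).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "AudioClip",
    "UnsupportedFormatError",
    "read_wav",
    "write_wav",
    "to_mono",
    "resample",
]

#: Minimum acceptable sample rate: below this the 2-8 kHz biophony band
#: would be truncated by Nyquist.
MIN_SAMPLE_RATE = 16_000


class UnsupportedFormatError(ValueError):
    """Raised for WAV encodings outside PCM 16/24/32-bit and IEEE float."""


@dataclasses.dataclass(frozen=True)
class AudioClip:
    """A uniformly sampled waveform.

    Parameters
    ----------
    samples:
        Float array of shape ``(n,)`` (mono) or ``(n, channels)``,
        amplitudes in ``[-1, 1]``.
    sample_rate:
        Sampling frequency in Hz (positive integer).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim not in (1, 2) or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D or 2-D array")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate", int(self.sample_rate))

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.sample_rate


_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0}


def read_wav(path: str | Path) -> AudioClip:
    """Read a RIFF/WAVE file into the canonical float representation.

    Supports 16/24/32-bit PCM and IEEE float encodings. 24-bit PCM is
    delivered by scipy as int32 with the low byte zero, so the int32 scale
    applies unchanged.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    IOError
        If the file is unreadable or truncated.
    UnsupportedFormatError
        For encodings outside the supported set (e.g. 8-bit PCM, ADPCM).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except ValueError as exc:
        raise UnsupportedFormatError(f"{path}: unsupported WAV encoding ({exc})") from exc
    except Exception as exc:  # truncated/corrupt RIFF chunks
        raise IOError(f"{path}: unreadable WAV file ({exc})") from exc
    if data.dtype == np.uint8:
        raise UnsupportedFormatError(f"{path}: 8-bit PCM is not supported")
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    if samples.size == 0:
        raise IOError(f"{path}: WAV file contains no samples")
    return AudioClip(samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, clip: AudioClip, encoding: str = "float32") -> None:
    """Write a clip as ``float32`` (default) or ``pcm16`` WAV."""
    path = Path(path)
    if encoding == "float32":
        data = clip.samples.astype(np.float32)
    elif encoding == "pcm16":
        # same full-scale convention as read_wav (divide by 32768), so a
        # write/read round trip stays within half an LSB away from +FS
        scaled = np.round(np.clip(clip.samples, -1.0, 1.0) * 32768.0)
        data = np.clip(scaled, -32768, 32767).astype(np.int16)
    else:
        raise ValueError(f"unknown encoding {encoding!r}; use 'float32' or 'pcm16'")
    wavfile.write(path, clip.sample_rate, data)


def to_mono(clip: AudioClip) -> AudioClip:
    """Average channels to mono. Mono input is returned unchanged."""
    if clip.samples.ndim == 1:
        return clip
    return AudioClip(samples=clip.samples.mean(axis=1), sample_rate=clip.sample_rate)


def resample(clip: AudioClip, target_rate: int) -> AudioClip:
    """Band-limited (polyphase) resampling to *target_rate* Hz.

    A no-op when rates already match. Duration is preserved to within one
    sample period of the coarser rate.
    """
    target_rate = int(target_rate)
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == clip.sample_rate:
        return clip
    g = np.gcd(clip.sample_rate, target_rate)
    up, down = target_rate // g, clip.sample_rate // g
    samples = resample_poly(clip.samples, up, down, axis=0)
    # polyphase output may overshoot full scale marginally at band edges
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        samples = samples / peak
    return AudioClip(samples=samples, sample_rate=target_rate)


def condition(clip: AudioClip, min_rate: int = MIN_SAMPLE_RATE) -> AudioClip:
    """Validate and convert a raw clip into analysis-ready mono form.

    Rejects clips sampled below *min_rate* because the biophony band would
    be cut off by Nyquist; mixes stereo down to mono.
    """
    if clip.sample_rate < min_rate:
        raise ValueError(
            f"sample rate {clip.sample_rate} Hz is below the minimum {min_rate} Hz "
            "needed to cover the 2-8 kHz biophony band"
        )
    return to_mono(clip)


def truncate_to(clip: AudioClip, n_samples: int) -> AudioClip:
    """Trim a clip to its first *n_samples* samples (survey length matching)."""
    if n_samples <= 0 or n_samples > clip.n_samples:
        raise ValueError(f"cannot truncate {clip.n_samples}-sample clip to {n_samples}")
    if n_samples == clip.n_samples:
        return clip
    return AudioClip(samples=clip.samples[:n_samples], sample_rate=clip.sample_rate)
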