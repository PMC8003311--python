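"""Short-time magnitude spectrograms and band-energy summaries.

Framing convention: frames are left-aligned, consecutive windows advance by
``hop`` samples, and a final partial window is dropped (no zero padding).
The matrix holds linear spectral magnitudes (not power, not dB); power
summaries square them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import get_window

from quietscape.audio_io import AudioClip

__all__ = ["Spectrogram", "spectrogram", "band_power"]


@dataclasses.dataclass(frozen=True)
class Spectrogram:
    """Time x frequency matrix of non-negative spectral magnitudes.

    ``values`` has shape ``(T, F)`` with T frames and F frequency bins;
    ``bin_freqs_hz`` spans 0..Nyquist inclusive.
    """

    values: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    frame_step_s: float
    window_len: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] < 2:
            raise ValueError("spectrogram needs a (T, F) matrix with T >= 2 frames")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ValueError("spectrogram magnitudes must be finite and non-negative")
        freqs = np.asarray(self.bin_freqs_hz, dtype=np.float64)
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("bin_freqs_hz must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_times_s", np.asarray(self.frame_times_s, dtype=np.float64))
        object.__setattr__(self, "bin_freqs_hz", freqs)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return float(self.bin_freqs_hz[-1])


def spectrogram(
    clip: AudioClip,
    window_len: int = 512,
    hop: int | None = None,
    window: str = "hamming",
) -> Spectrogram:
    """Short-time Fourier magnitude spectrogram of a mono clip.

    Parameters
    ----------
    clip:
        Mono clip to analyse.
    window_len:
        Analysis window length in samples (default 512).
    hop:
        Frame advance in samples; defaults to ``window_len``
        (non-overlapping frames, the convention of the R ecoacoustics
        toolchain this package cross-checks against).
    window:
        Taper name understood by :func:`scipy.signal.get_window`.
    """
    if clip.samples.ndim != 1:
        raise ValueError("spectrogram requires a mono clip; call to_mono first")
    if hop is None:
        hop = window_len
    if hop < 1:
        raise ValueError(f"hop must be >= 1, got {hop}")
    n = clip.n_samples
    if window_len > n:
        raise ValueError(f"clip has {n} samples, shorter than one {window_len}-sample window")
    n_frames = (n - window_len) // hop + 1
    if n_frames < 2:
        raise ValueError(
            f"clip yields only {n_frames} frame(s); at least 2 are needed for "
            "time-difference indices"
        )
    taper = get_window(window, window_len, fftbins=True)
    idx = np.arange(window_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = clip.samples[idx] * taper
    values = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(window_len, d=1.0 / clip.sample_rate)
    times = (np.arange(n_frames) * hop + window_len / 2) / clip.sample_rate
    return Spectrogram(
        values=values,
        frame_times_s=times,
        bin_freqs_hz=freqs,
        frame_step_s=hop / clip.sample_rate,
        window_len=window_len,
    )


def band_power(spec: Spectrogram, f_lo: float, f_hi: float) -> float:
    """Total spectral power in the half-open frequency band ``[f_lo, f_hi)``.

    Sums squared magnitudes over all frames and all bins whose center
    frequency satisfies ``f_lo <= f < f_hi``; half-open intervals make band
    partitions non-overlapping and exhaustive.
    """
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"invalid band [{f_lo}, {f_hi})")
    if f_lo > spec.nyquist_hz:
        raise ValueError(
            f"band [{f_lo}, {f_hi}) lies beyond the Nyquist frequency {spec.nyquist_hz} Hz"
        )
    mask = (spec.bin_freqs_hz >= f_lo) & (spec.bin_freqs_hz < f_hi)
    if not np.any(mask):
        raise ValueError(f"no spectrogram bins fall inside the band [{f_lo}, {f_hi}) Hz")
    return float(np.sum(spec.values[:, mask] ** 2))


def to_csv(spec: Spectrogram, path) -> None:
    """Debugging dump: frames x bins matrix with a header row of bin frequencies."""
    header = ",".join(f"{f:.3f}" for f in spec.bin_freqs_hz)
    np.savetxt(path, spec.values, delimiter=",", header=header, comments="")
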