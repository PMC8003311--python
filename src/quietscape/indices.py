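"""Per-recording scalar acoustic indices.

Implements the five indices the composite quietness assessment builds on:

* **ACI** — acoustic complexity index: per-bin, per-cluster normalized sum of
  absolute frame-to-frame intensity differences. High for amplitude-modulated
  biotic sound (birdsong), low for stationary noise (traffic).
* **NDSI** — normalized difference soundscape index: (beta - alpha) /
  (beta + alpha) with beta the biophony-band power (2-8 kHz here) and alpha
  the anthropophony-band power (1-2 kHz). Range -1..+1; +1 means the signal
  contains only biological sound.
* **ADI / AEI** — Shannon diversity and Gini evenness of per-band spectrogram
  occupancy above a dB threshold; mutually antagonistic.
* **LEQ_REL** — equivalent continuous level relative to full scale (dBFS),
  mapping to absolute dB SPL only through a user-supplied calibration offset.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any

import numpy as np

from quietscape.audio_io import AudioClip
from quietscape.spectral import Spectrogram, band_power, spectrogram

__all__ = [
    "AnalysisParams",
    "IndexResult",
    "aci",
    "ndsi",
    "adi",
    "aei",
    "leq_rel",
    "compute_all",
]


@dataclasses.dataclass(frozen=True)
class AnalysisParams:
    """Shared analysis settings; two index values are comparable only when
    produced with equal params.

    Defaults follow the conventions of the seewave/soundecology toolchain
    (512-sample non-overlapping Hamming windows, 5 s ACI clusters) except the
    NDSI bands, which are the urban-assessment choice of 1-2 kHz anthropophony
    vs 2-8 kHz biophony rather than the 1-2/2-11 kHz of the original NDSI
    literature.
    """

    window_len: int = 512
    hop: int | None = None
    window: str = "hamming"
    cluster_s: float = 5.0
    anthro_band: tuple[float, float] = (1000.0, 2000.0)
    bio_band: tuple[float, float] = (2000.0, 8000.0)
    adi_n_bands: int = 10
    adi_band_width: float = 1000.0
    adi_db_threshold: float = -50.0
    calibration_offset_db: float = 0.0

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["anthro_band"] = list(self.anthro_band)
        d["bio_band"] = list(self.bio_band)
        return d


@dataclasses.dataclass(frozen=True)
class IndexResult:
    """A named scalar index value plus the parameters that produced it."""

    name: str
    value: float
    params: dict[str, Any] = dataclasses.field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in {"ACI", "NDSI", "ADI", "AEI", "LEQ_REL"}:
            raise ValueError(f"unknown index name {self.name!r}")


def aci(spec: Spectrogram, cluster_s: float = 5.0) -> IndexResult:
    """Acoustic complexity index.

    Frames are partitioned into consecutive clusters of
    ``floor(cluster_s / frame_step_s)`` frames (a final partial cluster is
    dropped). Within cluster *j*, for each frequency bin *k*,

        d_jk = sum_t |I(t+1, k) - I(t, k)| / sum_t I(t, k)

    (0 when the denominator is 0, so silent bands contribute nothing), and
    ACI is the total of d_jk over all clusters and bins. The value is
    invariant to global amplitude scaling but grows with recording length,
    so only equal-duration recordings analysed with equal params compare.
    """
    if cluster_s < 2 * spec.frame_step_s:
        raise ValueError(
            f"cluster_s={cluster_s} s must be at least two frame steps "
            f"({2 * spec.frame_step_s:.4f} s)"
        )
    frames_per_cluster = int(cluster_s / spec.frame_step_s)
    n_clusters = spec.n_frames // frames_per_cluster
    if n_clusters == 0:
        # shorter than one full cluster: treat the whole recording as one
        frames_per_cluster = spec.n_frames
        n_clusters = 1
    if frames_per_cluster < 2:
        raise ValueError("every cluster holds fewer than 2 frames; ACI undefined")
    used = spec.values[: n_clusters * frames_per_cluster]
    clustered = used.reshape(n_clusters, frames_per_cluster, spec.n_bins)
    num = np.abs(np.diff(clustered, axis=1)).sum(axis=1)
    den = clustered.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    value = float(d.sum())
    return IndexResult(
        name="ACI",
        value=value,
        params={
            "cluster_s": cluster_s,
            "frames_per_cluster": frames_per_cluster,
            "n_clusters": n_clusters,
            "window_len": spec.window_len,
            "frame_step_s": spec.frame_step_s,
        },
    )


def ndsi(
    spec: Spectrogram,
    anthro_band: tuple[float, float] = (1000.0, 2000.0),
    bio_band: tuple[float, float] = (2000.0, 8000.0),
) -> IndexResult:
    """Normalized difference soundscape index (beta - alpha)/(beta + alpha).

    alpha is the anthropophony-band power, beta the biophony-band power.
    Total silence (alpha = beta = 0) is defined as 0 and flagged, keeping
    the downstream disturbance sign well-defined.
    """
    a_lo, a_hi = anthro_band
    b_lo, b_hi = bio_band
    if not (a_hi <= b_lo or b_hi <= a_lo):
        raise ValueError(f"bands {anthro_band} and {bio_band} overlap")
    alpha = band_power(spec, a_lo, a_hi)
    beta = band_power(spec, b_lo, b_hi)
    flags: tuple[str, ...] = ()
    if alpha == 0.0 and beta == 0.0:
        value, flags = 0.0, ("silent",)
    else:
        value = (beta - alpha) / (beta + alpha)
    return IndexResult(
        name="NDSI",
        value=value,
        params={"anthro_band": list(anthro_band), "bio_band": list(bio_band)},
        flags=flags,
    )


def _band_occupancy(
    spec: Spectrogram, n_bands: int, band_width: float, db_threshold: float
) -> np.ndarray:
    """Fraction of cells per contiguous band above db_threshold (dB rel. max)."""
    if n_bands < 2:
        raise ValueError(f"need at least 2 bands, got {n_bands}")
    if n_bands * band_width > spec.nyquist_hz:
        raise ValueError(
            f"{n_bands} bands x {band_width} Hz exceeds Nyquist {spec.nyquist_hz} Hz"
        )
    peak = float(spec.values.max())
    occ = np.zeros(n_bands)
    if peak == 0.0:
        return occ
    with np.errstate(divide="ignore"):
        level_db = 20.0 * np.log10(np.where(spec.values > 0, spec.values, np.nan) / peak)
    above = np.nan_to_num(level_db, nan=-np.inf) > db_threshold
    for i in range(n_bands):
        lo, hi = i * band_width, (i + 1) * band_width
        mask = (spec.bin_freqs_hz >= lo) & (spec.bin_freqs_hz < hi)
        if not np.any(mask):
            raise ValueError(f"no spectrogram bins inside occupancy band [{lo}, {hi}) Hz")
        occ[i] = above[:, mask].mean()
    return occ


def adi(
    spec: Spectrogram,
    n_bands: int = 10,
    band_width: float = 1000.0,
    db_threshold: float = -50.0,
) -> IndexResult:
    """Acoustic diversity index: Shannon entropy of normalized band occupancy.

    Ranges from 0 (one band holds all occupied cells, or silence) to
    ``ln(n_bands)`` (uniform occupancy).
    """
    occ = _band_occupancy(spec, n_bands, band_width, db_threshold)
    total = occ.sum()
    params = {"n_bands": n_bands, "band_width": band_width, "db_threshold": db_threshold}
    if total == 0.0:
        return IndexResult(name="ADI", value=0.0, params=params, flags=("silent",))
    q = occ / total
    nz = q[q > 0]
    value = float(-(nz * np.log(nz)).sum())
    return IndexResult(name="ADI", value=value, params=params)


def aei(
    spec: Spectrogram,
    n_bands: int = 10,
    band_width: float = 1000.0,
    db_threshold: float = -50.0,
) -> IndexResult:
    """Acoustic evenness index: Gini coefficient of raw band occupancies.

    0 when occupancy is perfectly even across bands, approaching 1 when it
    concentrates in a single band; negatively correlated with ADI.
    """
    occ = _band_occupancy(spec, n_bands, band_width, db_threshold)
    params = {"n_bands": n_bands, "band_width": band_width, "db_threshold": db_threshold}
    total = occ.sum()
    if total == 0.0:
        return IndexResult(name="AEI", value=0.0, params=params, flags=("silent",))
    x = np.sort(occ)
    n = len(x)
    # Gini via the sorted-rank identity
    value = float(2.0 * np.sum(np.arange(1, n + 1) * x) / (n * total) - (n + 1) / n)
    return IndexResult(name="AEI", value=value, params=params)


def leq_rel(clip: AudioClip, calibration_offset_db: float = 0.0) -> IndexResult:
    """Equivalent continuous level, dB relative to full scale.

    ``10 log10(mean(sample^2)) + offset``. With offset 0 this is dBFS; a
    calibration constant measured against a sound level meter maps it to
    absolute dB SPL. An all-zero clip is reported with value -inf and an
    explicit ``silent`` flag rather than left as a bare float.
    """
    if not math.isfinite(calibration_offset_db):
        raise ValueError("calibration_offset_db must be finite")
    mean_sq = float(np.mean(np.square(clip.samples)))
    params = {"calibration_offset_db": calibration_offset_db}
    if mean_sq == 0.0:
        return IndexResult(name="LEQ_REL", value=-math.inf, params=params, flags=("silent",))
    value = 10.0 * math.log10(mean_sq) + calibration_offset_db
    return IndexResult(name="LEQ_REL", value=value, params=params)


def compute_all(clip: AudioClip, params: AnalysisParams | None = None) -> dict[str, IndexResult]:
    """All five indices for one conditioned mono clip under shared params."""
    p = params or AnalysisParams()
    spec = spectrogram(clip, window_len=p.window_len, hop=p.hop, window=p.window)
    return {
        "ACI": aci(spec, cluster_s=p.cluster_s),
        "NDSI": ndsi(spec, anthro_band=p.anthro_band, bio_band=p.bio_band),
        "ADI": adi(spec, p.adi_n_bands, p.adi_band_width, p.adi_db_threshold),
        "AEI": aei(spec, p.adi_n_bands, p.adi_band_width, p.adi_db_threshold),
        "LEQ_REL": leq_rel(clip, p.calibration_offset_db),
    }
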