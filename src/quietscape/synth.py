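"""Seeded synthetic-soundscape generation.

Three source classes are emulated, following the standard soundscape
taxonomy:

* **biophony** — amplitude-enveloped linear-FM chirps (a birdsong stand-in)
  with Poisson-distributed onsets inside a 2-8 kHz band. The raised-cosine
  envelope gives the strong frame-to-frame intensity variability that the
  acoustic complexity index rewards.
* **anthropophony** — stationary band-limited Gaussian noise in 1-2 kHz with
  a constant envelope, the "road traffic" archetype.
* **geophony** — low-level broadband background noise.

Surveys place eight edge points and one core point; edges receive extra
anthropophony (``edge_anthro_boost_db``), emulating perimeter traffic. All
output is a pure function of (scenario, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np

from quietscape.audio_io import AudioClip, write_wav

__all__ = [
    "Scenario",
    "generate_biophony",
    "generate_anthropophony",
    "generate_geophony",
    "mix_clips",
    "render_point",
    "render_survey_clips",
    "render_survey",
]

#: Sentinel for a disabled (silent) noise source.
SILENT_DB = -np.inf


@dataclasses.dataclass(frozen=True)
class Scenario:
    """Synthetic-soundscape specification.

    Levels are dBFS of the component's RMS; ``-inf`` disables a component.
    ``edge_anthro_boost_db`` raises the anthropophony level at the eight edge
    points relative to the core, emulating perimeter traffic and edge-to-core
    attenuation. Identical (scenario, seed) pairs produce bit-identical audio.
    """

    duration_s: float = 60.0
    sample_rate: int = 22050
    bio_event_rate: float = 2.0
    bio_band: tuple[float, float] = (2000.0, 8000.0)
    bio_event_dur_s: tuple[float, float] = (0.1, 0.5)
    bio_level_db: float = 0.0
    anthro_level_db: float = -30.0
    anthro_band: tuple[float, float] = (1000.0, 2000.0)
    geo_level_db: float = SILENT_DB
    edge_anthro_boost_db: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.bio_event_rate < 0:
            raise ValueError("bio_event_rate must be >= 0")
        nyq = self.sample_rate / 2
        for name, (lo, hi) in (("bio_band", self.bio_band), ("anthro_band", self.anthro_band)):
            if not (0 <= lo < hi <= nyq):
                raise ValueError(f"{name} {lo, hi} must lie inside [0, {nyq}] Hz")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("bio_band", "bio_event_dur_s", "anthro_band"):
            d[key] = list(d[key])
        for key in ("anthro_level_db", "geo_level_db"):
            if not np.isfinite(d[key]):
                d[key] = None  # JSON-safe sentinel for a disabled source
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        for key in ("bio_band", "bio_event_dur_s", "anthro_band"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("anthro_level_db", "geo_level_db"):
            if d.get(key, 0) is None:
                d[key] = SILENT_DB
        return cls(**d)


def _chirp(sr: int, dur_s: float, f0: float, f1: float, amp: float) -> np.ndarray:
    """One linear-FM chirp with a raised-cosine (Hann) amplitude envelope."""
    n = max(int(dur_s * sr), 8)
    t = np.arange(n) / sr
    phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / dur_s * t**2)
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
    return amp * env * np.sin(phase)


def generate_biophony(scenario: Scenario, seed: int | None = None) -> AudioClip:
    """Intensity-varying chirp community inside the biophony band.

    Event onsets are Poisson(``bio_event_rate``) over the clip; each chirp's
    start and end frequencies are drawn uniformly inside the band (inset by
    a margin so envelope sidelobes stay in-band) and its duration uniformly
    from ``bio_event_dur_s``. Output is peak-normalized to at most 1.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sr = scenario.sample_rate
    n = int(scenario.duration_s * sr)
    out = np.zeros(n)
    n_events = rng.poisson(scenario.bio_event_rate * scenario.duration_s)
    lo, hi = scenario.bio_band
    # keep chirp energy comfortably inside the band despite FM + envelope spread
    margin = min(300.0, 0.1 * (hi - lo))
    for _ in range(n_events):
        dur = rng.uniform(*scenario.bio_event_dur_s)
        f0 = rng.uniform(lo + margin, hi - margin)
        f1 = np.clip(f0 + rng.uniform(-600.0, 600.0), lo + margin, hi - margin)
        amp = rng.uniform(0.3, 1.0)
        onset = int(rng.uniform(0, max(scenario.duration_s - dur, 0)) * sr)
        burst = _chirp(sr, dur, f0, f1, amp)
        end = min(onset + len(burst), n)
        out[onset:end] += burst[: end - onset]
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    out *= 10.0 ** (scenario.bio_level_db / 20.0)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return AudioClip(samples=out, sample_rate=sr)


def _bandlimited_noise(rng: np.random.Generator, n: int, sr: int, band: tuple[float, float],
                       level_db: float) -> np.ndarray:
    """Stationary Gaussian noise confined to *band* by spectral masking,
    scaled to an RMS of ``level_db`` dBFS."""
    if not np.isfinite(level_db):
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sr)
    lo, hi = band
    # raised-cosine roll-off inside the band edges: real noise sources have
    # soft spectral skirts, and hard edges smear badly under STFT analysis
    roll = min(50.0, 0.05 * (hi - lo))
    gain = np.zeros_like(freqs)
    flat = (freqs >= lo + roll) & (freqs < hi - roll)
    gain[flat] = 1.0
    lo_edge = (freqs >= lo) & (freqs < lo + roll)
    gain[lo_edge] = 0.5 * (1 - np.cos(np.pi * (freqs[lo_edge] - lo) / roll))
    hi_edge = (freqs >= hi - roll) & (freqs < hi)
    gain[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - (hi - roll)) / roll))
    shaped = np.fft.irfft(spec * gain, n)
    rms = np.sqrt(np.mean(shaped**2))
    if rms == 0.0:
        return np.zeros(n)
    target_rms = 10.0 ** (level_db / 20.0)
    return shaped * (target_rms / rms)


def generate_anthropophony(scenario: Scenario, seed: int | None = None) -> AudioClip:
    """Constant-envelope band-limited noise in the anthropophony band.

    Stationary by construction: frame-to-frame RMS varies well under 1 dB
    for frames of a few hundred samples. A level of ``-inf`` yields silence.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = int(scenario.duration_s * scenario.sample_rate)
    out = _bandlimited_noise(rng, n, scenario.sample_rate, scenario.anthro_band,
                             scenario.anthro_level_db)
    return AudioClip(samples=out, sample_rate=scenario.sample_rate)


def generate_geophony(scenario: Scenario, seed: int | None = None) -> AudioClip:
    """Broadband background noise at ``geo_level_db`` (disabled by default)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = int(scenario.duration_s * scenario.sample_rate)
    nyq = scenario.sample_rate / 2
    out = _bandlimited_noise(rng, n, scenario.sample_rate, (0.0, nyq), scenario.geo_level_db)
    return AudioClip(samples=out, sample_rate=scenario.sample_rate)


def mix_clips(*clips: AudioClip) -> AudioClip:
    """Sum equal-rate, equal-length clips; rescale only if the mix clips."""
    rates = {c.sample_rate for c in clips}
    lengths = {c.n_samples for c in clips}
    if len(rates) > 1 or len(lengths) > 1:
        raise ValueError("mix requires equal sample rates and lengths")
    total = np.sum([c.samples for c in clips], axis=0)
    peak = np.max(np.abs(total))
    if peak > 1.0:
        total /= peak
    return AudioClip(samples=total, sample_rate=clips[0].sample_rate)


def render_point(scenario: Scenario, seed: int, anthro_boost_db: float = 0.0) -> AudioClip:
    """One sampling point: biophony + (boosted) anthropophony + geophony."""
    seq = np.random.SeedSequence(seed)
    s_bio, s_anthro, s_geo = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(3)]
    boosted = dataclasses.replace(
        scenario, anthro_level_db=scenario.anthro_level_db + anthro_boost_db
    )
    return mix_clips(
        generate_biophony(scenario, seed=s_bio),
        generate_anthropophony(boosted, seed=s_anthro),
        generate_geophony(scenario, seed=s_geo),
    )


def render_survey_clips(scenario: Scenario, seed: int | None = None) -> dict[str, AudioClip]:
    """Nine role-keyed clips sharing one biophony community (common event
    rate, independent draws per point) with anthropophony boosted at edges."""
    base = scenario.seed if seed is None else seed
    seq = np.random.SeedSequence(base)
    point_seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(9)]
    roles = [f"edge{i}" for i in range(1, 9)] + ["core"]
    clips = {}
    for role, pseed in zip(roles, point_seeds):
        boost = scenario.edge_anthro_boost_db if role.startswith("edge") else 0.0
        clips[role] = render_point(scenario, pseed, anthro_boost_db=boost)
    return clips


def scenario_ladder(
    base: Scenario | None = None,
    anthro_levels_db: tuple[float, ...] = (SILENT_DB, -32.0, -26.0, -14.0, -7.0),
    bio_levels_db: tuple[float, ...] = (0.0, -1.0, -2.0, -3.0, -4.0),
) -> list[Scenario]:
    """A graded sequence of scenarios from quietest to noisiest.

    Level *i* raises the anthropophony and lowers the biophony relative to
    level *i-1*, emulating sites progressively more exposed to traffic; the
    biophony event rate is held fixed so sites differ in source levels, not
    community composition. Used for end-to-end parameter-recovery checks:
    the planted quietness order is the list order.
    """
    if len(anthro_levels_db) != len(bio_levels_db):
        raise ValueError("anthro and bio level ladders must have equal length")
    base = base or Scenario(duration_s=10.0)
    return [
        dataclasses.replace(base, anthro_level_db=a, bio_level_db=b)
        for a, b in zip(anthro_levels_db, bio_levels_db)
    ]


def render_survey(
    scenario: Scenario,
    area_name: str,
    out_dir: str | Path,
    seed: int | None = None,
    encoding: str = "float32",
) -> Path:
    """Render nine WAVs plus a survey manifest CSV; returns the manifest path.

    Also writes ``provenance.json`` (scenario + seed) so any output can be
    regenerated exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    used_seed = scenario.seed if seed is None else seed
    clips = render_survey_clips(scenario, seed=used_seed)
    rows = []
    for role, clip in clips.items():
        fname = f"{area_name}_{role}.wav"
        write_wav(out_dir / fname, clip, encoding=encoding)
        rows.append(f"{area_name},{role},{fname}")
    manifest = out_dir / f"{area_name}_manifest.csv"
    manifest.write_text("area_name,role,wav_path\n" + "\n".join(rows) + "\n")
    provenance = {"area_name": area_name, "seed": used_seed, "scenario": scenario.as_dict()}
    (out_dir / f"{area_name}_provenance.json").write_text(json.dumps(provenance, indent=2))
    return manifest
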