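import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quietscape.audio_io import AudioClip
from quietscape.indices import aci, adi, aei, leq_rel, ndsi
from tests.conftest import make_spectrogram


def aci_brute_force(values: np.ndarray, frames_per_cluster: int) -> float:
    """Independent triple-loop ACI: clusters x bins x frame pairs."""
    t_total, n_bins = values.shape
    n_clusters = t_total // frames_per_cluster
    if n_clusters == 0:
        n_clusters, frames_per_cluster = 1, t_total
    total = 0.0
    for j in range(n_clusters):
        block = values[j * frames_per_cluster:(j + 1) * frames_per_cluster]
        for k in range(n_bins):
            num = sum(abs(block[t + 1, k] - block[t, k]) for t in range(len(block) - 1))
            den = sum(block[t, k] for t in range(len(block)))
            if den > 0:
                total += num / den
    return total


class TestACI:
    def test_time_constant_spectrogram_is_zero(self):
        spec = make_spectrogram(np.tile([1.0, 2.0, 3.0], (6, 1)))
        assert aci(spec, cluster_s=6.0).value == 0.0

    def test_hand_worked_two_bin_example(self):
        """bin1 (1,3,1,3): (2+2+2)/8 = 0.75; bin2 constant: 0."""
        values = np.array([[1.0, 2.0], [3.0, 2.0], [1.0, 2.0], [3.0, 2.0]])
        spec = make_spectrogram(values, frame_step_s=1.0)
        assert aci(spec, cluster_s=4.0).value == pytest.approx(0.75, abs=1e-15)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 10), st.integers(4, 40),
           st.integers(2, 12))
    def test_matches_brute_force(self, seed, n_bins, n_frames, fpc):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 10, (n_frames, n_bins))
        values[rng.uniform(size=values.shape) < 0.2] = 0.0  # silent cells
        spec = make_spectrogram(values, frame_step_s=1.0)
        got = aci(spec, cluster_s=float(fpc)).value
        assert got == pytest.approx(aci_brute_force(values, fpc), rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**32 - 1),
           st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False))
    def test_amplitude_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, (12, 6))
        a = aci(make_spectrogram(values), cluster_s=6.0).value
        b = aci(make_spectrogram(values * scale), cluster_s=6.0).value
        assert b == pytest.approx(a, rel=1e-9)

    def test_cluster_too_short_rejected(self):
        spec = make_spectrogram(np.ones((10, 3)), frame_step_s=1.0)
        with pytest.raises(ValueError):
            aci(spec, cluster_s=1.0)

    def test_params_recorded(self):
        spec = make_spectrogram(np.ones((10, 3)))
        res = aci(spec, cluster_s=5.0)
        assert res.params["cluster_s"] == 5.0
        assert res.params["frames_per_cluster"] == 5


class TestNDSI:
    def test_constructed_band_powers(self):
        """alpha = 3, beta = 5 -> (5-3)/(5+3) = 0.25."""
        values = np.zeros((2, 41))
        values[0, 5] = math.sqrt(3.0 / 2)   # 1250 Hz, both frames
        values[1, 5] = math.sqrt(3.0 / 2)
        values[0, 10] = math.sqrt(5.0)      # 2500 Hz
        spec = make_spectrogram(values, nyquist_hz=10000)
        res = ndsi(spec)
        assert res.value == pytest.approx(0.25, abs=1e-12)

    def test_pure_bio_band_energy_is_plus_one(self):
        values = np.zeros((3, 41))
        values[:, 12] = 2.0  # 3000 Hz only
        assert ndsi(make_spectrogram(values, nyquist_hz=10000)).value == 1.0

    def test_pure_anthro_band_energy_is_minus_one(self):
        values = np.zeros((3, 41))
        values[:, 6] = 2.0  # 1500 Hz only
        assert ndsi(make_spectrogram(values, nyquist_hz=10000)).value == -1.0

    def test_equal_band_powers_give_zero(self):
        values = np.zeros((2, 41))
        values[:, 6] = 1.0
        values[:, 12] = 1.0
        assert ndsi(make_spectrogram(values, nyquist_hz=10000)).value == 0.0

    def test_silence_defined_as_zero_and_flagged(self):
        res = ndsi(make_spectrogram(np.zeros((3, 41)), nyquist_hz=10000))
        assert res.value == 0.0
        assert "silent" in res.flags

    def test_overlapping_bands_rejected(self):
        spec = make_spectrogram(np.ones((2, 41)), nyquist_hz=10000)
        with pytest.raises(ValueError, match="overlap"):
            ndsi(spec, anthro_band=(1000, 3000), bio_band=(2000, 8000))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        spec = make_spectrogram(rng.uniform(0, 3, (4, 41)), nyquist_hz=10000)
        assert -1.0 <= ndsi(spec).value <= 1.0


def _occupancy_matrix(band_frames: dict[int, int], n_frames: int = 4) -> np.ndarray:
    """Matrix over 10 x 1 kHz bands (4 bins each, Nyquist 10 kHz): band i has
    its bins lit in the first band_frames[i] frames."""
    values = np.zeros((n_frames, 41))
    for band, frames in band_frames.items():
        values[:frames, 4 * band:4 * band + 4] = 1.0
    return values


class TestADIAEI:
    def test_uniform_occupancy_maximizes_adi(self):
        values = _occupancy_matrix({i: 4 for i in range(10)})
        res = adi(make_spectrogram(values, nyquist_hz=10000))
        assert res.value == pytest.approx(math.log(10), abs=1e-12)

    def test_single_band_gives_zero_adi(self):
        values = _occupancy_matrix({3: 4})
        assert adi(make_spectrogram(values, nyquist_hz=10000)).value == 0.0

    def test_two_equal_bands_give_ln2(self):
        values = _occupancy_matrix({0: 2, 1: 2})
        res = adi(make_spectrogram(values, nyquist_hz=10000))
        assert res.value == pytest.approx(math.log(2), abs=1e-12)

    def test_silent_spectrogram_adi_zero_flagged(self):
        res = adi(make_spectrogram(np.zeros((4, 41)), nyquist_hz=10000))
        assert res.value == 0.0
        assert "silent" in res.flags

    def test_uniform_occupancy_gives_zero_aei(self):
        values = _occupancy_matrix({i: 4 for i in range(10)})
        assert aei(make_spectrogram(values, nyquist_hz=10000)).value == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_occupancy_gini(self):
        """One of ten bands occupied: Gini = 0.9."""
        values = _occupancy_matrix({5: 4})
        res = aei(make_spectrogram(values, nyquist_hz=10000))
        assert res.value == pytest.approx(0.9, abs=1e-12)

    def test_adi_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            values = rng.uniform(0, 1, (6, 41))
            res = adi(make_spectrogram(values, nyquist_hz=10000))
            assert 0.0 <= res.value <= math.log(10) + 1e-12

    def test_band_layout_beyond_nyquist_rejected(self):
        spec = make_spectrogram(np.ones((2, 41)), nyquist_hz=8000)
        with pytest.raises(ValueError):
            adi(spec, n_bands=10, band_width=1000)


class TestLeqRel:
    def test_full_scale_square_wave_is_zero_dbfs(self):
        clip = AudioClip(samples=np.tile([1.0, -1.0], 500), sample_rate=22050)
        assert leq_rel(clip).value == pytest.approx(0.0, abs=1e-12)

    def test_full_scale_sine_is_minus_3db(self):
        n = 22050
        t = np.arange(n) / 22050
        clip = AudioClip(samples=np.sin(2 * np.pi * 100 * t), sample_rate=22050)
        assert leq_rel(clip).value == pytest.approx(10 * math.log10(0.5), abs=1e-3)

    def test_halving_amplitude_drops_6db(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, 4096)
        full = leq_rel(AudioClip(samples=x, sample_rate=22050)).value
        half = leq_rel(AudioClip(samples=x / 2, sample_rate=22050)).value
        assert full - half == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_silent_clip_flagged(self, silence):
        res = leq_rel(silence)
        assert res.value == -math.inf
        assert "silent" in res.flags

    def test_calibration_offset_applied(self):
        clip = AudioClip(samples=np.ones(100), sample_rate=22050)
        assert leq_rel(clip, calibration_offset_db=94.0).value == pytest.approx(94.0)
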