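# Methods

## Model and assumptions

The package treats "urban quietness" as a property of the soundscape's
structure rather than its loudness. Three assumptions carry the method:

1. Biotic sound (chiefly birdsong) is strongly amplitude-modulated, so the
   acoustic complexity index (ACI) — the per-bin, per-cluster normalized sum
   of absolute frame-to-frame spectrogram differences — is high where
   biophony is rich and low where stationary anthropogenic noise dominates.
2. Anthropogenic and biological sound occupy largely disjoint spectral bands
   in cities: 1–2 kHz for traffic-like sources, 2–8 kHz for biophony. The
   NDSI band-power ratio (β − α)/(β + α) then signs the balance between them.
3. A genuinely quiet area is *spatially* coherent: complexity at its core
   should match its perimeter. The nine-point protocol (8 edge + 1 core
   recordings of equal duration) summarizes this as CB = mean-edge-ACI /
   core-ACI, RG_ACI = nine-point ACI range, AD = sign of the nine-point mean
   NDSI, and CUQI = AD × (RG_ACI × CB).

Degenerate cases are pinned down explicitly: AD is defined as 0 when the mean
NDSI is exactly 0 (the sign fraction is otherwise undefined there), NDSI of
total silence is defined as 0 and flagged, a zero-ACI core raises an error
rather than yielding an infinite CB (a silent core indicates a broken
measurement, not infinite quietness), and an all-zero clip reports its
relative Leq with an explicit `silent` flag.

## Analysis parameters

| parameter | default | why |
|---|---|---|
| STFT window / hop | 512 / 512 samples, Hamming | the non-overlapping convention of the seewave/soundecology R toolchain, keeping values cross-comparable |
| ACI cluster | 5 s | the customary cluster length for ACI; final partial cluster dropped |
| NDSI bands | [1, 2) kHz vs [2, 8) kHz | the urban-assessment band choice (not the 2–11 kHz of the original NDSI literature); half-open so partitions are exact |
| ADI/AEI | 10 bands × 1 kHz, −50 dB rel. max | conventional occupancy settings |
| minimum sample rate | 16 kHz | Nyquist must cover the 8 kHz biophony edge |
| canonical rate | 22.05 kHz | smallest common rate comfortably covering 2–8 kHz |

All parameters are serialized into every output, and two index values are
treated as comparable only when their parameter sets are equal. Because raw
ACI totals scale with frame count, surveys truncate all nine clips to the
shortest duration before extraction.

## Synthetic soundscapes

The generator emulates the three standard source classes:

- **Biophony**: linear-FM chirps (0.1–0.5 s, raised-cosine envelope, centers
  drawn uniformly inside 2–8 kHz with a ≤300 Hz inset margin), onsets
  Poisson at `bio_event_rate`. Defaults: 2 events/s, 60 s clips at 22.05 kHz.
  An optional `bio_level_db` gain scales the whole chirp community; ACI is
  amplitude-invariant, so this moves NDSI without moving ACI.
- **Anthropophony**: stationary Gaussian noise spectrally confined to
  1–2 kHz with a 50 Hz raised-cosine skirt at each band edge (real traffic
  has soft spectral edges; hard edges also smear badly under short-window
  analysis). RMS is calibrated to `anthro_level_db` dBFS (default −30);
  −inf disables the source. Its envelope is constant to <1 dB at 0.5 s
  frames.
- **Geophony**: broadband noise, disabled by default.

Sampling points mix the three; edges receive `edge_anthro_boost_db` extra
anthropophony (default +6 dB) as a single scalar — the protocol distinguishes
only edge vs core, so no geometric attenuation model is attempted. Mixes that
would clip are renormalized, which (deliberately, like a recorder's gain
staging) compresses level differences near full scale. Identical
(scenario, seed) pairs are bit-identical; per-point and per-source seeds are
spawned from one seed sequence.

What the generator does **not** emulate: real species vocalizations, reverb
and terrain acoustics, weather, diurnal cycles, and broadband traffic energy
above 2 kHz. Passing tests therefore demonstrate the *mechanics* of the
indices and the composite score under controlled band-separated conditions,
not field performance on real urban recordings, where band overlap makes
NDSI and ACI noisier.

## Numerical choices

- The spectrogram is linear magnitude (ACI's input); band powers square it
  (NDSI's input). Frames are left-aligned and a final partial window is
  dropped — no padding, so silence stays exactly zero.
- ACI bins with zero cluster energy contribute 0 instead of raising, so a
  silent band cannot poison a recording. Clips shorter than one cluster are
  treated as a single cluster.
- NDSI endpoints on synthesized audio are attained only up to short-time
  Fourier leakage across the shared 2 kHz band edge: about 2 × 10⁻⁵ below +1
  for pure biophony and 1 × 10⁻³ above −1 for pure anthropophony with the
  default window. Endpoint tests assert at 10⁻³ / 5 × 10⁻³ accordingly;
  the exact ±1 values are verified separately on constructed spectrograms
  whose off-band power is identically zero.
- AEI uses the sorted-rank Gini identity; a one-hot occupancy over n bands
  gives (n−1)/n exactly.
- PCM16 writing uses the symmetric full-scale convention (scale 2¹⁵, clamp
  at 2¹⁵−1) so write/read round trips stay within one LSB.
- Ranking breaks CUQI ties by area name, making output independent of input
  order.

## Parameter-recovery experiment

`synth.scenario_ladder` defines five scenarios from quietest to noisiest:
anthropophony at −inf/−32/−26/−14/−7 dBFS and biophony gain 0/−1/−2/−3/−4 dB
at a fixed event rate. The spacing places the AD sign flip mid-ladder.
Biophony is graded by level rather than event rate because ACI is
amplitude-invariant while the nine-point ACI range *anti*-correlates with
event density (sparser communities spread more across points) — grading the
rate would make the planted order unrecoverable by construction. The
acceptance suite runs 20 seeded ladders of 10 s clips and checks that the
mean NDSI falls monotonically, AD flips exactly once per ladder, and the mean
per-ladder Spearman correlation between planted order and CUQI exceeds 0.8.

Two structural properties of CUQI surface here and are worth knowing when
interpreting scores. First, among surveys whose mean NDSI is negative, louder
anthropophony *shrinks* |CUQI| (masking compresses the ACI range), so the
index orders negative-scored areas by proximity to neutrality, not by
loudness. Second, CUQI grows with CB even though CB > 1 is itself read as a
complexity-poor core; the formula is implemented exactly as defined and this
tension is left to the analyst.

## Problem sizes

Simulation-based tests use 10 s clips for the ladder experiment, 30 s for
spatial-balance replicates, and 3 s for the 200-clip ADI/AEI antagonism
scan; these lengths give stable statistics for the effects under test while
keeping the default suite fast. The acceptance script uses 10 s clips for
the NDSI extremes and a 60 s clip for the CB identity.

## Known limitations

- No calibration linkage between recordings and sound-level-meter readings is
  recoverable without a user-supplied offset; Leq is relative (dBFS).
- Only the 8-edge + 1-core area shape is supported.
- The NDSI biophony band follows the 2–8 kHz urban convention; recordings
  dominated by biophony above 8 kHz (some insects) will be under-credited.
- Field-scale claims (correlations with noise maps, multi-area hierarchies on
  real cities) are outside what the synthetic validation can establish.
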