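# Methods

## Scope

pulmokit implements a complete pediatric lung-sound classification
pipeline (denoise → 6-s window → MFCC → majority-voting SVM ensembles →
stratified/nested cross-validation → metrics and rater comparison) plus
a synthetic auscultation-audio generator used as the data source for
development and testing. Reading ICBHI-2017-style annotated recordings
is supported for external data; the package never downloads data.

## Synthetic auscultation audio

### What the generator emulates

Each clip is a vesicular (normal breath-sound) base plus
class-conditional adventitious events, optional heart sounds, and an
ambient white-noise floor, peak-normalized to 0.9.

**Breath envelope.** The amplitude envelope rises through inspiration
(quarter-sine) to a single per-cycle maximum at the
inspiration/expiration boundary, decays (quarter-cosine) over the first
60 % of expiration, and sits at a floor of 0.1 in late expiration. This
matches the clinical picture of vesicular sound heard mainly during
inspiration and early expiration. The inspiratory fraction is drawn
from U(0.30, 0.45).

**Vesicular base.** White Gaussian noise through a 2nd-order
Butterworth low-pass whose −3 dB point is exactly the configured corner
(default 200 Hz, the textbook energy drop of vesicular sound),
multiplied by the breath envelope. The measured corner of a single
6-s realization (Welch PSD, 4096-sample segments, ~10 Hz smoothing,
sustained-drop criterion with linear interpolation at the crossing)
scatters within roughly ±15 % of the nominal value.

**Wheezes.** Sinusoids with weak 2nd/3rd harmonics (0.25/0.08 relative
amplitude) and slow sinusoidal frequency drift of up to ±5 %, Tukey
tapered. Each wheezing clip carries 1–2 wheezes placed in inspiratory
and/or expiratory phases, covering 30–90 % of the phase. Durations are
additionally floored at 100 ms: at the respiratory-rate truncation
bound (80/min) a 30 % coverage of a short inspiratory phase could
otherwise fall below the 80 ms definitional minimum for a wheeze.
Center frequencies are drawn from U(200, 900) Hz, inside the
definitional 100–1000 Hz band with margin for the ±10 % spectral-peak
tolerance.

**Crackles.** Damped sinusoids `exp(−t/τ)·sin(2πft)` with unit analytic
envelope; τ = duration/3.1 so the envelope is below 5 % of its peak at
the nominal duration (`exp(−3.1) ≈ 0.045`). Defaults: fine 650 Hz /
5 ms, coarse 350 Hz / 15 ms, each jittered ±10 % in frequency and
±20 % in duration in corpus generation. 3–10 crackles are placed per
inspiratory segment (90 % inspiratory, 10 % spilling into early
expiration) — crackle counts and placement are not reported clinically,
so these defaults were chosen to reproduce the familiar spectrogram
morphology (short broadband bursts clustered in inspiration).

**Heart sounds.** S1 (~45 Hz, louder) at every multiple of the beat
period and S2 (~55 Hz, 0.45× amplitude) at 30 % of the period,
as damped oscillations with ±10 % per-beat amplitude jitter. Present
with probability 0.75 (heart sounds are audible in three quarters of
pediatric clips); heart rate U(80, 160) bpm, a pediatric range chosen
because no clinical heart-rate distribution is available for this
setting.

**Event loudness.** Event amplitudes are expressed relative to the RMS
of the vesicular base: wheezes U(1.0, 2.5), crackles U(3.0, 6.0),
heart sounds 1.5. No clinical loudness data exist for this corpus;
these values make the three classes acoustically separable without
being trivial (10-fold SVM accuracies in the high 0.8s to mid 0.9s, not
1.0), which is the stated purpose of the generator.

**Corpus statistics.** Clip length and respiratory rate are drawn from
truncated normals — length: mean 4.1 s, sd 1.8 s on [1.5, 10] s; rate:
mean 30.2/min, sd 13.4 on [12, 80]/min. Truncating an asymmetric
interval shifts the mean, so the location parameter is solved
(moment matching) such that the *truncated* mean equals the target;
sample means of large corpora then converge to 4.1 s and 30.2/min. The
truncation bounds keep draws physiologic. The truncated sd is somewhat
below the nominal sd; only the means are treated as calibration
targets. Cycle count (1 or 2) is derived as `round(length·rate/60)`
clipped to {1, 2}, which reproduces a predominance of 2-cycle clips.
The ambient noise floor is drawn from U(15, 30) dB SNR relative to the
composed signal.

### What it does not emulate

Heart murmurs, conversational background noise, and stethoscope contact
artifacts (such clips are excluded from clinical corpora before
analysis, so the generator does not produce them); airway-mechanical
coupling between events and the breath signal; inter-patient variation
beyond the parameter draws; psychoacoustic realism beyond the spectral
and temporal targets above. Consequently, passing tests demonstrate
that the pipeline recovers class structure whose spectral/temporal
signatures match the definitional parameters — not that it would reach
the same accuracy on real pediatric recordings, which carry correlated
noise, label ambiguity, and physiological diversity the generator does
not model.

### Determinism

Every clip is generated from its own integer seed (recorded in the
manifest); a corpus is a deterministic function of (config, seed), and
WAV output is byte-identical across reruns. Child seeds are derived
with `numpy.random.SeedSequence` spawning so sub-components (vesicular
noise, events, heart sounds) are independent streams.

## Preprocessing

**Denoising** is BayesShrink soft-threshold wavelet shrinkage: noise σ
estimated from the finest detail band as `median(|d|)/0.6745`,
per-subband threshold `σ_noise²/σ_signal` where
`σ_signal = sqrt(max(E[d²] − σ_noise², 0))`. The implementation
delegates to `skimage.restoration.denoise_wavelet`; a test recomputes
the thresholds directly with PyWavelets and checks agreement to 1e−12.
Default wavelet sym8 with `floor(log2 n) − 6` levels capped to [1, 6] —
enough decomposition to reach the sub-200 Hz bands where lung-sound
energy lives. Denoising is applied to the full clip *before*
windowing.

**Windowing** converts any clip to exactly 6 s (1–4 breaths across the
pediatric-to-adult respiratory-rate range): clips ≥ 6 s are cropped to
their first 6 s; shorter clips are concatenated with whole copies of
themselves until longer than 6 s, then cropped. The operation is
idempotent. Windows are peak-normalized so features are invariant to
recording gain (a desirable property for stethoscope pipelines; the
choice is ours — gain handling is typically unspecified).

## Features

40 MFCCs per frame with FFT window 660 samples, hop 512, Hann window,
centered frames with reflect padding (frame count = ⌊n/hop⌋ + 1 =
517 for a 6-s window at 44.1 kHz). The mel filterbank uses 128
area-normalized triangular filters on the HTK mel scale
(`2595·log10(1 + f/700)`); the filterbank size and mel variant are
unstandardized choices, documented here and fixed by tests. Cepstra are
an orthonormal DCT-II of the dB-scaled (`10·log10`, floor 1e−10) mel
power spectrum; the floor makes silent input deterministic (constant
coefficient 0, zeros elsewhere).

The 40×517 matrix is aggregated to a fixed-length vector. Default
`mean_std` (80-dim: per-coefficient temporal mean, then sd) keeps the
dimension small relative to realistic sample sizes; `flatten` and
`mean_only` are available.

## Classifier

Four binary tasks: (1) normal vs. abnormal, (2) crackles vs. wheezing,
(3) normal vs. crackles, (4) normal vs. wheezing. Task 1 maps both
adventitious classes to "abnormal"; tasks 2–4 drop the absent class.

Each task uses a majority-voting ensemble of RBF-kernel SVMs with
default sizes 1, 4, 10, 4 for tasks 1–4. Members differ by seeded
bootstrap resamples of the training rows (bagging — the minimal
diversity mechanism consistent with majority voting); each member is a
StandardScaler + SVC(C=1, gamma='scale', probability) pipeline.
Standardization is fit per member on its own resample; without it the
large-magnitude low-order cepstral coefficients dominate the RBF
distance. Members emit Platt-calibrated probabilities.

**Voting.** A member votes for the class with probability > 0.5; the
majority wins. Even splits are broken by the higher mean member
probability (≥ 0.5 → positive class). The degenerate 1-member ensemble
is therefore the member's probability thresholded at 0.5 — note this
can differ from `SVC.predict` near the boundary, since Platt scaling is
fit by internal cross-validation.

**Nested overall ensemble.** After K-fold cross-validation, the K fold
ensembles' members are pooled into one ensemble of K × n_members SVMs
with the unchanged voting rule; this is the model evaluated on
prospective-style data.

## Evaluation

Stratified K-fold (default K = 10, delegated to scikit-learn's
`StratifiedKFold` with shuffling): per-fold class counts deviate from
the proportional share by < 1 sample. Pooled metrics are computed over
the union of validation predictions, equivalently the sum of per-fold
confusion counts.

Metrics default to macro averaging over the two classes (a single
per-task precision/recall/F1 with accuracy ≠ precision is consistent
with macro averaging; positive-class averaging is available because the
convention is ambiguous). Zero-denominator ratios are reported as 0
with an explicit flag rather than dropped.

Rater comparison is a Pearson chi-square on the 2×2 correct/incorrect
table, 1 df, with optional Yates continuity correction (off by default;
the uncorrected statistic is the common choice at these sample sizes,
and identical proportions short-circuit to statistic 0, p = 1).

## Visualization

Mel-spectrograms are rendered as log-power images with an 80 dB
dynamic-range floor. UMAP embeddings (n_neighbors = 20,
min_dist = 0.3, cosine metric) are seeded for reproducibility even
though fixing the random state disables parallel layout — testability
outranks embedding aesthetics here. The embedded vectors are the same
80-dim feature vectors fed to the SVMs.

## Problem sizes and numerical choices

The end-to-end pipeline default is 300 internal clips (100 per class)
and a 90-clip prospective-style batch split 28/31/31, generated from a
disjoint seed stream. Property tests use 300-clip corpora over three
seeds; unit and determinism tests use reduced corpora (30 clips, K = 3)
— size choices made to keep the suite fast while leaving the acceptance
properties at the full default conditions. Spectral measurements in
tests use Welch averaging with sustained-drop detection to avoid
false corners from single-bin noise. Tie-breaks, log floors, and
zero-denominator conventions are fixed values documented above so that
every code path is deterministic given seeds.

## Known limitations

- Synthetic-data results bound what can be claimed about clinical
  performance (see "What it does not emulate").
- The MFCC-to-vector aggregation is a package convention; published
  pipelines often leave it unspecified, so absolute accuracies are not
  comparable across implementations.
- `(1,1)` ICBHI cycles (crackle and wheeze both present) are excluded
  from three-class tasks; they are counted separately in composition
  reports.
- The ensemble-size search (1–10 members) is exposed but not automated;
  defaults follow the published task-specific sizes.
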