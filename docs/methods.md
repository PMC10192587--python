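# Methods

`audiosfa` tests a single idea end to end: that the identity of a natural
auditory "object" — a vocalization, a texture, a burst of noise — can be
learned without supervision from nothing but the *temporal regularity* of a
cochlea-like representation, i.e. from which spectral patterns and which
inter-channel correlation patterns change slowly. This note records the
model, the synthetic stimulus design, the numerical choices, and what the
package's tests do and do not establish.

## The pipeline

1. **Stimulus** — a mono waveform (synthetic; see below).
2. **Cochlear model** — 42 fourth-order gammatone filters with centre
   frequencies spaced on the ERB-rate scale from 22.9 Hz to 20 208 Hz at the
   50 kHz reference rate (the hearing range of the rhesus macaque); per
   channel, the band envelope (Hilbert magnitude) is smoothed by a temporal
   kernel formed as the difference of two gamma kernels
   `g(n) = a n^m exp(-b n)` (g1: a=1.5, b=0.04, m=2; g2: a=1.0, b=0.036,
   m=2; n in samples at 50 kHz, ~10 ms support), and the result is z-scored
   over the presentation. The z-score makes the representation invariant to
   global amplitude rescaling.
3. **Feature learning** — one of:
   - **lSFA**: linear slow feature analysis. Minimize
     `Delta_i = <(df_i/dt)^2>` over affine projections of the 42 channels,
     under zero-mean, unit-variance, decorrelation constraints.
   - **qSFA**: the same optimization over quadratic polynomials
     `Q_i = x^T V_i x` with symmetric `V_i` — 903 independent quadratic
     coefficients over 42 channels (945 monomial columns including the
     linear terms; the constant is absorbed by mean subtraction). The
     quadratic space matters because pairwise products carry the
     *correlation* structure between channels.
   - **PCA** (maximum variance) and **FastICA** (maximum independence,
     3 components — the stimuli contain at most three sources) as baselines.
4. **Classifier** — every non-gap time point of the presentation is
   projected into the top features (5 by default) and a linear SVM (C = 1)
   is trained on stratified random 75/25 splits, 30 splits per repeat,
   5 repeats with a fresh feature fit each; chance is 50 %. Two linear
   references bracket the methods: an upper bound (SVM on all 42 channels)
   and a null model (SVM on 5 random channels, redrawn per pair).

SFA is solved by mean subtraction, SVD whitening with rank truncation at a
relative singular value of 1e-7, and an eigendecomposition of the
covariance of the first-differenced whitened signal; the time derivative is
the first difference times the frame rate. Feature signs are fixed by
making each feature's largest-magnitude loading positive. Equivalence with
the direct generalized eigenproblem `A w = lambda B w` (A the
difference covariance, B the covariance) is verified to 1e-8 relative on
small instances.

## Temporal-regularity metrics

Two modulation spectra quantify the two kinds of continuity:

- **Component continuity**: the 2-D FFT power of the log-amplitude
  spectrogram (25 ms Hann window, 5 ms hop; floor at 1e-6 of peak; global
  mean subtracted, the standard modulation-power-spectrum convention). The
  marginal over temporal modulation (mean across spectral modulations,
  clipped to ±80 Hz, normalized to sum 1) is read as an empirical
  probability density over modulation frequency.
- **Correlation continuity**: the same construction applied to the
  time-varying vector of windowed Pearson correlations between all channel
  pairs (strict upper triangle). Two deliberate differences from the
  component case:
  - *non-overlapping* 50 ms windows (window = hop). With overlapping
    windows the estimation noise of the *white-noise reference* is itself
    low-passed by the window, concentrating the reference marginal at low
    modulations and destroying the contrast the measure exists to capture.
    With independent windows the reference stays spectrally flat.
  - *no mean subtraction* before the FFT. A temporally constant, nonzero
    correlation is the extreme of correlation continuity and must appear in
    the 0 Hz bin; subtracting the mean would leave only estimation noise
    for a perfectly stationary correlation structure.

The **kurtosis score** of a category is the kurtosis of its marginal
(weighted, non-excess convention: Gaussian → 3) divided by that of white
noise. Values above 1 mean modulation power more concentrated at low
frequencies than noise. The bias-corrected variant
`k0 = (n-1)/((n-2)(n-3)) ((n+1) k1 - 3(n-1)) + 3` is available and verified
against the standard textbook estimator; an unweighted variant (kurtosis of
the raw power vector) is provided for sensitivity analysis. As a reference
point, the Laplace/Gaussian kurtosis ratio is 6/3 = 2.

## Synthetic stimuli

The generators emulate the statistical structure the analysis consumes, not
the acoustics of any real species:

- **Vocalization events** (0.1–3 s): "harmonic" preset — a stack of 8
  harmonics of a fundamental that drifts as a smooth random walk in log
  frequency (excursion 0.25 octaves, band-limited at 4 Hz), each harmonic
  carrying an independent slowly varying log-normal amplitude envelope
  (cutoff 4 Hz); "broadband" preset — a flat-spectrum noise carrier under a
  common slow envelope. Exemplars differ in pitch (log-normal spread of
  0.5 octaves around the 400 Hz class centre), as voices do. Both presets
  have continuous components *and* continuously varying correlations.
- **Clutter**: 20 events drawn with replacement, placed uniformly at random
  so each fits entirely inside a 3-s token, summed at unit gain, then
  amplitude-regularized — divided by the 50 ms-smoothed Hilbert envelope
  and rescaled to the original RMS, which raises the trough-to-median
  envelope ratio and prevents classification from exploiting silent gaps in
  the background.
- **Applause-like texture**: a Poisson train (100 clicks/s) of 4 ms
  broadband noise transients. Components are discontinuous (click onsets),
  but because every transient excites all channels coherently the
  correlation pattern is temporally stable: component kurtosis score ≈ 1.4
  (near noise) while the correlation score ≈ 2.6 — the signature
  dissociation between the two continuity types.
- **White noise**: i.i.d. Gaussian at −20 dBW (variance 0.01), the
  reference for all kurtosis scores and the control stimulus class.

Mixtures place a signal inside a clutter token with the background gain
chosen so that `log10(P_signal / P_clutter) = SNR` exactly (base 10 chosen
for the unspecified logarithm; configurable), over the study sweep −7
(essentially no signal) to +3 (essentially no background). Pair
presentations use a random order and a silent gap uniform in 5–50 % of the
first stimulus's duration; gap samples (and, after decimation, frames whose
receptive field straddles a label transition — a 20 ms guard) are excluded
from classification.

What the generators do **not** reproduce: formant structure, articulation,
species-specific call morphology, room acoustics, recording noise, or the
spectral shape of real claps. Passing tests therefore demonstrate that the
pipeline's orderings hold for signals with the stated continuity structure,
not that the exact accuracies on any natural corpus would be reproduced.

## Problem sizes and the scaled configuration

The reference front end operates at 50 kHz. Analysis experiments run on a
scaled configuration chosen once for desk-scale experimentation: stimuli
generated at 8 kHz, filterbank spanning 22.9 Hz to 0.95×Nyquist with the
same 42 channels, cochleagram decimated to a 4 kHz frame rate, 0.5-s
stimuli, and ensembles of 30–50 pairs with 1–2 repeats. The temporal kernel
keeps its physical ~10 ms time course at every rate (its parameters are
defined per sample at 50 kHz; the filter models the ear, so its shape must
not stretch with the analysis rate — stretching it smooths noise envelopes
so strongly that quadratic SFA can extract a near-perfect time ramp from a
white-noise pair and "discriminate" it perfectly by position).

A related capacity caveat is inherited honestly rather than hidden: with
~2 000–5 000 frames per presentation against 945 quadratic dimensions, qSFA
retains some ability to encode elapsed time, which inflates its accuracy
relative to a full-scale run (where T/dim ≈ 50). The ensemble orderings
(upper bound ≥ qSFA ≥ lSFA > chance; vocalizations ≫ white-noise pairs;
accuracy rising with test SNR) are the quantities the package asserts, not
the absolute percentages.

## Numerical choices

- Gammatone filters are cascades of four identical two-pole resonators
  (pole radius `exp(-2π·1.019·ERB(fc)/fs)`), unit gain at centre. A single
  8th-order transfer function is numerically unstable for the 22.9 Hz
  channel at 50 kHz.
- Whitening rank truncation at 1e-7 relative singular value (the quadratic
  space is rank-deficient for short presentations).
- Convolution with the temporal kernel uses mode "same" with zero padding;
  kernel support truncated at 1e-6 of peak magnitude.
- Decimation uses polyphase resampling (anti-aliased, zero-phase).
- z-scores use the population variance denominator; normalization is per
  presentation (the concatenated pair, or the mixture when clutter is
  present).
- Degenerate inputs raise: silence through the cochlear model (zero
  variance), all-zero waveforms in the amplitude regularizer, zero-variance
  data in the kurtosis estimator; a zero-variance channel inside one
  correlation window only zeroes that window's pairs with a logged warning.
- Seeds: a single master seed is fanned out to named streams
  (CRC-32 of the stream tokens mixed into a NumPy SeedSequence), so any
  stage can be rerun in isolation; every generator is a pure function of
  (parameters, seed).

## Known limitations

- Single temporal filter (no modulation filterbank), no middle-ear stage,
  no adaptation or compression beyond envelope extraction.
- ICA features have no natural ranking; the 3-component choice follows the
  source-count argument and FastICA occasionally needs restarts (seeded,
  deterministic; failure after three restarts raises).
- The correlation-modulation marginal is limited to ±10 Hz by the 50 ms
  non-overlapping windows; the component marginal reaches ±80 Hz.
- Kurtosis scores compare categories only on a shared modulation grid;
  token durations must match between a category and its noise reference.
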