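# Methods

## The analysis

`voxfrail` implements a vocal-biomarker analysis of frailty in older
adults.  A sustained /a/ phonation of about one second, sampled at
10 kHz with 16-bit depth, is reduced to four scalar voice parameters:

* **A1 — average zero-crossing rate.**  Sign changes between
  consecutive samples, counted per 25 ms frame and divided by the frame
  length in samples; A1 is the mean over frames (dimensionless, in
  [0, 1]).  Frames tile the signal without overlap and each frame owns
  the L sample-to-sample gaps starting at its first sample: overlapped
  or gap-dropping layouts alias against periodic signals whose crossing
  spacing divides the hop, which biases the frame mean (for a pure sine
  the estimator must return 2·f0/fs, and does, to within 2.5% across
  50–500 Hz).  Exact zero samples inherit the previous sign so a
  crossing is never double-counted.
* **A2 — variation of local peaks and valleys.**  Local maxima and
  minima are detected over the whole utterance with a minimum spacing
  of half the estimated glottal period (autocorrelation f0), after a
  zero-phase low-pass at 450 Hz; candidate extrema below 25% of the
  90th-percentile height are discarded as inter-cycle ripple.  A2 is
  the average of the peak and valley mean absolute deviations, in
  full-scale amplitude units.  The band-limiting exists because raw
  waveform peak heights reflect F1 ringing and additive noise far more
  than cycle-to-cycle amplitude instability; on the low-harmonic band
  the cycle crest scales directly with the glottal pulse amplitude.
  "Average deviation" is read as mean absolute deviation (switchable to
  SD via `AcousticConfig.deviation`).
* **A3 — variation of the first and second formant frequencies.**
  Per 25 ms frame (10 ms hop): pre-emphasis 0.97, Hamming window,
  autocorrelation-method LPC of order 2 + fs/1000 (12 at 10 kHz), roots
  of the prediction polynomial converted to (frequency, bandwidth)
  pairs, kept when the bandwidth is under 400 Hz and the frequency lies
  in 90–4000 Hz; the two lowest surviving frequencies are (F1, F2).
  A3 is the average of the F1 and F2 mean absolute deviations over
  valid frames, in Hz, requiring at least five valid frames.
* **A4 — spectral energy ratio.**  Fraction of Welch-periodogram power
  (Hamming, 25 ms segments, 50% overlap, DC bin excluded) above the
  end frequency of 3 kHz.  Defined only for sample rates above 6 kHz.

Participants are scored on three frailty indices — CHS (Fried
phenotype; frail at ≥ 3 of 5 criteria), SOF (frail at ≥ 2 of 3), and
FRAIL (frail at 3–5 of 5) — from raw criterion fields (grip strength,
gait speed, chair-stand ability, questionnaire answers, weight change,
drug count).  Boundary conventions follow the operational wording:
weakness and slowness use strict `<` cut-offs (28/18 kg by sex,
1.0 m/s), CHS weight loss is unintentional and ≥ 4.5 kg or > 5%/year,
SOF weight loss is > 5% regardless of intent, FRAIL weight loss is
≥ 5%, and polypharmacy is ≥ 8 drugs.  All cut-offs live in
`FrailtyThresholds`.  A missing criterion contributes 0, is reported,
and flags the assessment incomplete when it could change the category.
Participants who cannot walk count as slow.

The association layer fits, for each feature × index (× sex stratum),
a univariate maximum-likelihood logistic regression of the binary
outcome *frail vs robust/pre-frail* on the scaled feature.  Odds
ratios are reported per conventional unit: per 1 for A1, per 0.1 for A2
and A4, per 10 Hz for A3.  Confidence intervals are Wald on the
log-odds scale (exp(b ± 1.96·SE)); perfect separation falls back to a
Jeffreys-penalized (Firth) fit flagged `converged=False`.  Probability
conversion uses p = odds/(1 + odds).  Screening ANOVAs (two groups) and
a count(%)/mean±SD descriptive table with chi-square/Fisher/ANOVA tests
complete the output set.  Models are deliberately unadjusted and no
multiple-testing correction is applied to decisions (a Bonferroni
column is emitted for reference).

## The synthetic data generator

No recordings ship with the package; everything downstream is validated
against a source–filter vowel synthesizer with known ground truth.

**Voice model.**  A glottal pulse train at f0 (default 128 Hz) receives
per-cycle multiplicative Gaussian jitter (period) and shimmer
(amplitude), clipped at ±3 SD to avoid period collapse.  Spectral tilt
is a one-pole low-pass applied twice (≈ −12 dB/oct above ~500 Hz).  The
source drives a cascade of second-order resonators at the formant
centers/bandwidths (default 700/1200/2600 Hz for /a/).  F1 and F2
centers follow a mean-reverting Gaussian wander updated every 10 ms,
reflected at ±20% of the nominal center, with ~30 ms correlation time:
a free random walk was rejected because its realized per-recording
excursion varies so much that the extracted formant deviation only
weakly reflects the configured drift scale.  High-pass (> 3 kHz) noise
is added at a configurable power relative to the vowel.  Output is
peak-normalized to 0.9 and fully determined by the seed.

**Calibration.**  Each feature is paired with one knob — A1 ↔ F1
center (600–950 Hz; the zero-crossing rate of a vowel tracks its
dominant resonance), A2 ↔ shimmer, A3 ↔ drift scale, A4 ↔ relative HF
noise power.  The knob→feature response curves are measured once per
session by sweeping each knob over a fixed grid (three seeds per
point), monotonicized, and inverted by interpolation; the responses of
the *other* three features along each sweep are kept as cross-talk
curves and subtracted before inversion (resolution order A4 → A3 → A1
→ A2).  A raw target outside the achievable interval raises an error
naming that interval.  Over isolated 50-point grids the
synthesize-then-extract Spearman correlation exceeds 0.8 for every
feature.  Under full cohort conditions extracted A2/A3/A4 track their
targets well (ρ ≈ 0.8/0.9/1.0), while extracted A1 tracks its target
only weakly: the noise power that realizes a participant's A4 target
moves the zero-crossing rate more than the F1 span can offset.  This
is a documented limitation; the study conditions never place an effect
on A1, so no recovery property depends on it.

**Cohort model.**  Frailty status is drawn at the configured prevalence
(default 0.18; cohort defaults n = 277, 63.2% female).  Acoustic
targets are drawn from the Gaussian-discriminant construction
x | status ~ N(μ + status·δ, σ²) with δ = ln(OR)/unit · σ², under which
the implied *univariate* logistic slope per reporting unit is exactly
ln(OR) — avoiding the non-collapsibility bias a joint conditional
model would introduce.  Optional sex-interaction modifiers multiply a
feature's OR within one sex.  Criterion fields are then filled
consistently with the latent status: frail participants have shuffled
criteria activated until all three indices reach their thresholds
(remaining flags Bernoulli(0.15)); non-frail participants draw sparse
flags and deactivate one at random while any index sits at threshold.
The scorers therefore reproduce the latent status exactly, which the
tests assert.  Baseline feature means/SDs (A1 0.18 ± 0.011,
A2 0.010 ± 0.003, A3 18 ± 6 Hz, A4 0.10 ± 0.035) sit inside the
synthesizer's achievable ranges with ~3 SD of headroom.  Per-participant
random streams come from counter-based seed splitting
(`SeedSequence(seed, spawn_key=(i,))`), so enlarging a cohort never
reshuffles earlier participants.

**What the generator does not emulate.**  Perceptual vowel quality,
intonation, recording-channel effects, pathological voice types
(diplophonia, aperiodicity), and any correlation structure among
features beyond the synthesis cross-talk.  A passing recovery test
shows the pipeline estimates what the generator encodes; it does not
certify the clinical associations themselves.

## Numerical choices and problem sizes

* LPC instability (non-positive prediction error, |reflection
  coefficient| ≥ 1) marks a frame invalid rather than raising.
* Degenerate two-group ANOVA (zero within-group variance, distinct
  means) returns F = 1e12, p = 0 instead of infinity.
* Logistic fits require n ≥ 20, both outcome classes, and predictor
  variation; strata violating these are reported `estimable=False`.
* The alternating-peak A2 hand example equals 0.1 exactly with the
  analysis low-pass disabled and to within 2e-3 under the default
  band-limited analysis (band-limiting perturbs discrete-time peak
  samples by well under the measure's printed precision).
* Simulation-based checks use: Wald coverage 100 replicates at
  n = 1000; parameter recovery 20 replicates at n = 500 with 1.0 s
  audio; null calibration 200 replicates at n = 200 with 0.6 s audio
  (the type-I rate is invariant to recording duration under the null;
  the shorter vowels keep the check proportionate).

## Known limitations

* Numeric equivalence with any particular external analysis software is
  not claimed; the original measure definitions leave frame length,
  pooling, and deviation conventions open, and the choices here are
  documented above and exposed in configuration.
* A2's absolute scale depends on the fraction of low-band energy in the
  normalized waveform, so it is comparable across recordings analyzed
  with the same settings but not across different low-pass choices.
* The Firth fallback reports Wald intervals from the penalized
  information matrix; profile-likelihood intervals are not implemented.
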