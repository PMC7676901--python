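# Methods

`eeglisten` re-creates, as tested and reusable code, a complete analysis
chain for multichannel EEG recorded while people listen to speech in
environmental noise: per-condition feature extraction (band powers, spectral
shape, alpha peak, long-range temporal correlations), PCA dimension
reduction, mixed-effect modelling of component scores, and prediction of
information-retention (exam) z-scores.  Because raw listening-study EEG of
this kind is rarely shareable, the package ships a synthetic-cohort
generator that plants known ground truth for every quantity the pipeline
estimates; all tests are parameter-recovery and oracle checks against that
ground truth.

## The synthetic world

### Signal model

Each channel of a generated fragment is

    x(t) = b(t) + sum_k w_k(region) * A_k * m_k(t) * cos(phi_k(t))

* **Background** `b(t)`: Gaussian noise with a one-sided PSD proportional to
  `1/f^a` (default exponent `a = 1`, configurable in [0, 2]), synthesized in
  the frequency domain.  Its total power over 1–45 Hz is the
  `background_power` parameter (default 50 µV², a typical broadband scalp
  EEG power).  Per-band multiplicative gains on this spectrum plant
  condition-dependent band powers.
* **Oscillators**: each oscillator is a unit-amplitude carrier
  `cos(phi(t))` whose instantaneous frequency wanders slowly around
  `center_hz` with a Gaussian spread of `bandwidth_hz / 2` (low-passed
  Gaussian noise), multiplied by a strictly positive amplitude envelope

      m(t) = max(1 + 0.5 * z(t), 0.05),

  where `z` is unit-variance fractional Gaussian noise (fGn) with the
  requested Hurst exponent, generated exactly by circulant embedding
  (Davies–Harte).  With modulation depth 0.5 the floor truncates about 3%
  of samples; the residual bias this leaves in the planted exponent is
  within the DFA estimator's own finite-size bias (both are pinned by
  recovery tests at the 0.03–0.05 level).  `A_k` scales the oscillator so its band-integrated
  power equals `peak_power` (default 30 µV², a clear but realistic alpha
  bump over the default background).

  *Why an FM carrier and not amplitude-normalized narrowband noise*: noise
  normalized to constant modulus keeps phase slips; their broadband clicks
  re-enter the Hilbert envelope after band-pass filtering and destroy a
  planted envelope exponent (measured: H = 0.8 recovered as ≈ 0.64).  With
  the FM carrier the planted envelope *is* the Hilbert envelope of the
  oscillation, exactly.
* **Topography** is per-subregion gains (`region_weights`), not a forward
  head model: the downstream inference only ever uses six scalp subregions.

### Cohort design

Defaults mirror a realistic listening study: 23 participants, three tasks —
lecture attended (LA, 5-minute fragments), background attended (BA) and
background unattended (BUA, 3-minute fragments each) — and four background
sounds (pink noise PK, i.e. lecture in silence, only during LA;
multi-talker MT; highway HW; fluctuating traffic FT).  Per participant, the
13 LA topics receive backgrounds by rotating the background list with the
participant index, which spreads backgrounds over topics and guarantees
every topic is heard in pink noise by about a quarter of the cohort (the
exam reference requires at least two pink presentations per topic, hence
`n_participants >= 2 * n_backgrounds`).

Condition and participant structure is planted on latent features (Hurst
exponent of the alpha envelope; log alpha bump power; log background power;
per-band log power gains): every latent is `base + fixed_shift(task,
background) + participant intercept + fragment jitter`, with Gaussian
participant intercepts (SD `participant_sd`, default 0.1) and fragment
jitter (SD `fragment_sd`, default 0.1).  The Gaussian choice for
inter-participant variability is a modelling default, not an empirical
claim.  All randomness derives from a single cohort seed through spawned
`SeedSequence` substreams, so cohorts are bit-reproducible.

### Exam scores

Keyword counts per (participant, topic) are a rounded, clipped linear
function of the standardized planted latents (slopes `exam_weights`, in
keywords per latent SD), plus a per-topic base difficulty drawn once from
U(8, 16), a participant intercept, and Gaussian noise (`exam_noise_sd`,
default 1.5 keywords).

### What the generator does not emulate

Acoustically realistic audio, event-locked (ERP-style) structure, eye/muscle
artifacts, volume conduction and realistic channel covariance, non-Gaussian
participant effects.  A green end-to-end test therefore establishes that the
estimators recover what they claim from signals obeying the stated model —
not that the pipeline is robust to every artifact of real recordings (the
judgment-based cleaning steps of real studies are deliberately out of
scope; recordings carry user-supplied exclusion lists instead).

## Preprocessing

Re-referencing subtracts the chosen reference channel (nose by default).
Resampling is polyphase FIR (anti-aliased) to 512 Hz; band-pass is a
Hamming-windowed sinc of order 3380 (0.5–134 Hz), applied as a single
linear-phase pass with group-delay compensation — zero-phase timing without
squaring the magnitude response.  Whether the original analysis used
zero-phase filtering is not documented anywhere we know; spectral features
are phase-insensitive, and envelope timing (which DFA needs) is preserved
by the delay compensation, so this choice is safe on both counts.  The
audio/EEG delay is the argmax of the cross-correlation between the recorded
sound channel and the presented audio (ties broken toward the smallest
absolute lag; positive lag = audio arrives late in the recording), and all
scalp channels are shifted by the estimated delay before fragment
splitting.

## Feature extraction

* **Welch PSD**: 1 s Hamming windows, 0.5 s overlap, zero-padded so the
  grid spacing is 0.03125 Hz (2^14 bins at 512 Hz; at other rates the bin
  count adapts to keep that resolution).  Density scaling: the rectangle
  integral of the PSD equals the signal variance.
* **Band powers**: absolute power is the rectangle integral over half-open
  bins `[f_lo, f_hi)` — delta 1–4, theta 4–8, alpha 8–13 (plus 7–13 and
  lower/upper halves), beta 13–30, gamma 30–45, wide 1–45 Hz — so the five
  canonical bands partition 1–45 Hz and their relative powers sum to one
  exactly.  RPTA is theta power over alpha power.
* **Spectral shape** per band: centre of gravity CF, bandwidth B as the
  root second central spectral moment (the source text only names
  "bandwidth"; the second-moment convention is adopted and pinned by
  tests), and SEF95, the smallest grid frequency below which 95% of band
  power lies.
* **Root-MUSIC alpha peak** (`MF2713/MP2713`, `MF2813/MP2813`): the signal
  is band-passed 7–13 or 8–13 Hz with an order-2 Butterworth (one causal
  pass; a forward–backward pass would square the skirt tilt it imposes on
  near-edge peaks), decimated to ~64 Hz so the 64 autocorrelation lags span
  about a second, and the noise-subspace polynomial of the 64×64
  autocorrelation matrix is rooted.  Among the P = 2 subspace roots the
  positive-frequency line of maximum power (solved from the signal-space
  eigenvalues) is returned; MP is the power of the real oscillation, so it
  scales with amplitude squared.  A root outside the band is clipped to the
  edge and flagged.
* **Individual alpha frequency**: on a PSD with ≤ 0.1 Hz spacing, a line is
  fitted to ln p over 1–20 Hz *excluding 7–14 Hz* (so the bump cannot bias
  the aperiodic slope), the detrended spectrum `s = p − exp(p2 + f·p1)` is
  fitted with a single Gaussian (initialized at the largest detrended value
  in 8–13 Hz, centre bounded to [7, 14] Hz, width to [0.1, 5] Hz), and the
  fit is accepted when the peak `a1 + z(b1)` exceeds the upper 95%
  prediction bound of the aperiodic baseline,
  `exp(y0(b1) + 1.96·sigma_resid)`.  The individual alpha interval is
  `[TF, |5 − (f_alpha − 1)| + f_alpha]` with TF the raw-spectrum power
  minimum between 4 Hz and the peak; IAF is the centre of gravity of the
  *detrended* spectrum on that interval, recomputed once after updating the
  upper edge from the first IAF.  Computing the centre of gravity on the
  raw spectrum instead would re-import the 1/f background the procedure
  just removed and biases the estimate by ~0.3 Hz on a realistic bump —
  hence the detrended convention, pinned by a recovery test.  When the
  Gaussian bump is not accepted, the feature table falls back to the
  root-MUSIC peak so that rows stay complete.
* **DFA / LRTC** (`SEV1`, `SEV2`): 8–13 Hz Hamming FIR of order 0.25 s
  (128 taps at 512 Hz, delay-compensated), Hilbert amplitude envelope,
  cumulative sum of the mean-removed envelope, windows of log-spaced sizes
  (20 per decade) placed from sample 0 with 50% overlap (tail remainders
  discarded), linear least-squares detrending per window, fluctuation =
  mean of window standard deviations, and the scaling exponent as the
  ordinary least-squares slope of log fluctuation vs log size inside
  5–18 s.  Calculation ranges 2.5–180 s (SEV1) and 0.1–180 s (SEV2), both
  capped at fragment length.  Exponents between 0.5 and 1 flag long-range
  temporal correlations.

### Known statistical limits of the DFA stage

Two properties matter when reading SEV values and green tests:

1. **Sampling noise.** With the 5–18 s fitting interval on a 180 s
   fragment, the top scale holds only ~19 half-overlapping windows and the
   detrended windows of a self-similar profile each carry O(1) effective
   degrees of freedom, so the seed-to-seed SD of the recovered exponent is
   ≈ 0.07 — for any DFA variant (checked against an independent minimal
   reimplementation and a weighted-fit variant).  Recovery *bias* is below
   0.01 across H in [0.5, 0.85].
2. **SNR shrinkage.** The deliberately short 0.25 s band-pass is leaky;
   broadband background passing through it adds an uncorrelated component
   to the extracted envelope and shrinks the measured exponent toward 0.5.
   At the default oscillator-to-background ratio the shrinkage is ≈ 0.15 at
   H = 0.8; the planted envelope itself is exact (a dedicated test pins
   both facts).  End-to-end recovery is therefore validated in a
   strong-alpha regime (bump 40 µV² over 4 µV² background), and the
   end-to-end exam-prediction test runs in the same regime.

## PCA

Absolute and peak powers are mapped to natural log; every column is
z-scored with the sample (n−1) SD; `X = U S V^T` by SVD.  Scores are `X V`,
explained variance fractions `s_i^2 / Σ s^2`, and component signs are fixed
by making each loading vector's largest-magnitude element positive.
Feature coordinates on a component are feature–score correlations.  Two
normalizations of squared coordinates are exposed, because both appear in
practice: `contributions` (per component, summing to 100% within each
component) and `representation_quality` (per feature across the retained
components, summing to 100% within each feature row).  Subregion scores are
arithmetic means of raw channel-level scores within each of the six scalp
subregions (frontal, central, left/right temporal, parietal, occipital);
the channel→subregion table follows the usual lobe boundaries and is
overridable.  Nine components are carried into the statistics stage; PCA is
fitted once on the pooled matrix over all conditions.

## Statistics

* **Mixed models** are fitted with statsmodels `MixedLM` (participant
  random intercept), by maximum likelihood whenever AIC or likelihood-ratio
  comparisons follow (REML only for final coefficient reporting).  AIC is
  `−2 logLik + 2 edf` with `edf` counting fixed coefficients + random
  intercept variance + residual variance; the identity is enforced
  structurally, so AIC values are comparable across the model family.
  Singular fits (random variance → 0) are kept and flagged.
* **Tukey post-hoc**: estimated marginal means of a factor are balanced
  averages of design rows over the other model terms; all pairwise
  contrasts are tested against the studentized-range distribution with
  residual degrees of freedom (a containment-style approximation for mixed
  fits).  Under a planted null the fraction of significant pairs stays at
  the nominal family-wise level (pinned by simulation).
* **Within-background / within-task families**: one mixed model per
  (component, background) of score ~ task + subregion, and per (component,
  task) of score ~ background + subregion, each with a Tukey table rendered
  in the triangular layout (upper triangle p-values, lower triangle arrows
  toward the larger mean, diagonal max/min).
* **Exam z-scores**: per topic, mean and sample SD of keyword counts over
  the pink-noise rows of all participants standardize every row of that
  topic.  Zero pink SD flags the topic (z undefined); fewer than two pink
  rows is an error.
* **Exam prediction**: constant, background-type, full-EEG (k components ×
  6 subregions of LA subregion scores, merged per participant × topic) and
  backward-AIC-stepwise models, as plain or participant-random-intercept
  regressions.  Backward elimination drops, at each step, the term whose
  removal lowers AIC the most, stopping when no removal lowers it —
  deterministic given the data (a formula-free OLS fast path makes the
  54-predictor search cheap).  Nested pairs are compared by likelihood
  ratio (χ², df = edf difference); non-nested pairs report ΔAIC only.
  Exam rows enter per topic (not averaged per background); this is
  configurable upstream by aggregating the exam table.

## Pipeline and formats

`simulate → preprocess → extract → pca → model`, driven by one TOML-able
configuration whose hash stamps every output; identical (config, seed)
reruns are bit-identical.  Recordings are written as EDF (16-bit) or BDF
(24-bit) by a minimal built-in reader/writer (1 s records, uniform rate);
manifests, feature tables, scores and model tables are CSV; ground truth is
CSV + JSON sidecar.  The `preprocess` stage only materializes fragment EDFs
for inspection — extraction streams the same preprocessing, so the default
stage list skips it.

## Numerical choices and degenerate inputs

Half-open band bins avoid double counting shared edges; constant channels,
constant envelopes, all-zero bands, non-positive powers before log,
constant feature columns, missing pink references and out-of-range
fragments all raise informative errors rather than propagating NaN.
Gaussian-fit non-convergence or absence of a local alpha maximum yields an
unaccepted IAF, not an exception.  PCA sign fixing, the z-score ddof, the
Tukey df approximation and the stepwise tie behaviour (first minimum wins)
are all pinned by tests.

## Known limitations

Six-subregion gains instead of head-model topography; no artifact
synthesis; the IAF acceptance bound construction follows the stated rule
but other toolboxes may decide differently near the threshold; DFA SD and
shrinkage limits above; EDF writer supports one uniform sampling rate and
no annotations.
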