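# Methods

This note documents the models, estimators and numerical choices behind
`mcgurk_ecog`: a pipeline for asking whether the high-gamma
representation of spoken syllables in auditory cortex follows the heard
sound or the seen mouth articulation, and in which direction stimulus
information travels along the superior temporal gyrus (STG).

## Task model and timeline

All epoch times are in seconds relative to **audio onset** (t = 0).  A
trial consists of one second of silent articulation video (video onset
t = −1.0), a 500 ms audio syllable (t = 0 to 0.5) and one second of
post-audio video.  Four video syllables ("BA", "GA", "VA", "THA") cross
four audio syllables, giving 16 stimulus combinations; the subject then
reports which syllable they heard (four-alternative forced choice,
chance 0.25).  Epochs span [−2.0, +1.5] s so that a stimulus-free
baseline second precedes the video.

Stimulus combinations are grouped behaviorally:

* **matched** — video and audio share the syllable;
* **mcgurk** — incongruent, and the *video* identity is reported more
  often than chance;
* **unmatched** — incongruent, and the *audio* identity is reported
  more often than chance;
* **unclassified** — neither criterion reached (excluded from category
  analyses); combinations significant for both are resolved by the
  larger report fraction.

"More often than chance" is operationalized as a one-sided exact
binomial test against 0.25 at α = 0.05, per combination.  The exact
test is the minimal-assumption choice at per-combination sample sizes
(≈10 trials); note it cannot reject below 3 trials per combination
(min tail 0.0625), and at 10 trials it needs ≥6 video reports.

## Synthetic-data generator

The generator (`synth`) is first-class, tested code: it defines the
study conditions under which every downstream claim is verified.

**Background.**  Each electrode carries independent 1/f-power Gaussian
noise (spectral shaping of white noise, flattened below 1 Hz), total SD
40 µV — the broadband statistics of cortical field potentials without
biophysical detail.

**Phoneme code.**  Per seed, each syllable receives a fixed random
spectro-temporal template: three carrier frequencies drawn from
80–190 Hz and a smooth random amplitude envelope supported on
[−1.0, +0.5] s (video onset to syllable end).  Three designated STG
electrodes — posterior, middle (primary-auditory-proximal) and anterior
— each realize this template on every trial with independent carrier
phases, per-trial lognormal amplitude (σ = 0.5), carrier jitter
(σ = 10 Hz) and latency jitter (σ = 80 ms).  The jitter emulates
induced (non-phase-locked) high-gamma, whose single-trial variability
is large; it also keeps single-electrode decoding off ceiling, which
matters because an information-difference measure is blind between two
saturated electrodes.  Template amplitude is set so that burst RMS
equals `snr` × the background RMS *within 75–200 Hz* (default
snr = 1).  On incongruent trials the realized template follows
`code_carrier` (default `video` — the illusion regime).

All three coding electrodes carry the code at equal base SNR.  This is
deliberate: the tendency statistic below reduces to a difference of the
two electrodes' marginal informations, so a code present on one
electrode only would register as a large directed asymmetry even
without any coupling, leaving no null regime to test against.

**Directed coupling.**  The source electrode's burst realization is
added to the destination electrode, delayed by `coupling_lag`
(default 50 ms), scaled by `coupling_gain` (default 2.0) and masked
(20 ms cosine edges) to one task interval (default the video-only
second, posterior→middle).  The destination thus receives two
independent-noise realizations of the stimulus pattern inside the
coupling interval — more stimulus information, which is exactly the
lagged redundancy the conditional-information analysis detects.  The
default gain makes the planted effect clearly detectable (≈ +0.1–0.35
bits) without saturating the destination electrode.

**Evoked response.**  All three coding electrodes receive an
audio-onset-locked, syllable-independent response: a slow damped
deflection (8 Hz, τ = 150 ms, ≈120 µV, ×1.6 on the middle electrode —
the physiological marker of the electrode nearest primary auditory
cortex) plus a brief broadband high-gamma burst (Gaussian envelope at
80 ms, amplitude 1.5 × band-noise RMS).  It anchors electrode selection
and the middle-electrode role assignment but carries no identity
information.

**Behavior.**  Congruent trials report the audio identity.  Incongruent
trials report the video identity with probability `mcgurk_prob`
(default 0.8), otherwise the audio identity with a 10% lapse rate
spread over the two remaining alternatives.

**What the generator does not emulate** — and hence what passing tests
do not show about patient data: anatomical topography and volume
conduction, non-stationary background (epileptiform activity, state
changes), phase-locked low-frequency syllable coding, realistic
articulatory feature structure shared across phonemes, and behavioral
attention lapses correlated with neural state.  Recovery results here
mean the *estimators* work, not that cortical data must behave this
way.

## Preprocessing

Common-average re-referencing subtracts the per-sample mean across
electrodes (per hemisphere when metadata says so).  The 500 Hz low-pass
is a linear-phase Hamming FIR applied forward–backward (zero net phase,
≈106 dB stopband after the two passes), followed by integer decimation
to 1 kHz (polyphase resampling for non-integer ratios); the filter
doubles as the anti-alias filter, so `lowpass_hz ≤ target_fs/2` is
enforced.  Zero-phase filtering matters because the transfer analysis
is latency-sensitive.  A cutoff at exactly the new Nyquist rate is
nudged 0.5% below it (FIR design constraint); only the topmost band
edge is affected.

## Multitaper spectrograms

A 500 ms window advanced in 10 ms steps, time-bandwidth product NW = 7
with the K = 11 leading Slepian tapers (K ≤ 2NW−1), yielding ±14 Hz
analysis bandwidth.  Power is the taper-averaged one-sided PSD
(µV²/Hz); Parseval calibration is verified in tests.  Window centers
define the time axis and windows that would extend beyond the epoch are
dropped — no padding, so the −1..1 s difference statistic never sees
edge artifacts.  Band normalization z-scores each frequency row by its
own mean and SD over a stimulus-free baseline (default: window centers
in [−1.75, −1.25] s, the pre-video second); a row constant at its
baseline mean maps to zeros, while zero baseline variance with real
deviations is an error.

The difference statistic between two mean spectrograms is the mean of
|A − B| over all cells with −1 ≤ t ≤ 1 s.  For each McGurk-labeled
combination (video v, audio a) it is computed against the matched
combination sharing the video (v,v) and the one sharing the audio
(a,a); under a video-borne code the same-video statistic is the smaller
one.  The two pooled samples (combination × electrode) are compared
with a two-sided Mann-Whitney U test.

## Electrode selection

Electrodes are ranked by trial-averaged 75–200 Hz power during the
1000 ms from audio onset (ties toward lower index), restricted to
STG-flagged electrodes when the metadata flag exists — the in-silico
stand-in for the anatomical constraint.  The middle (AI-proximal) role
comes from metadata when present, otherwise from the largest mean
evoked potential in the 500 ms after audio onset.

## Pairwise decoding

Features per trial: for each selected electrode, the raw voltage trace
over [−1.0, +0.5] s concatenated with the unwrapped log-power
(10·log₁₀) spectrogram cells whose 500 ms analysis windows lie fully
inside that span (50 ms step for features — the 500 ms window already
smooths over that scale, and the coarser step keeps the feature count
tractable).  Log power is used because spectral power is heavily
right-skewed and the discriminant assumes roughly Gaussian classes.

Per syllable pair: trials split into two stratified, seeded folds.
Per fold, using training-half statistics only: per-column z-scoring
(zero-variance columns dropped and counted), PCA keeping the minimal
number of leading components whose cumulative explained variance
reaches 95%, then a two-class LDA with equal priors and Ledoit-Wolf
shrinkage (features ≫ trials makes the pooled covariance singular, so
some regularization is implied).  Folds are interchanged and confusion
counts pooled.  Fold metadata records component counts and
training-fold statistics so the absence of train/test leakage is
testable.

**Scoring on illusion trials.**  `decode_stimulus_identity(target)`
trains on the target attribute's labels and yields the qualitative
ordering (a video-borne code decodes video well and audio near chance,
and the reverse under an audio-borne code).  The below-chance audio
effect, however, cannot arise from a classifier trained and scored on
the same labeling: on incongruent trials whose video and audio both lie
in the pair the two labelings are complementary, and LDA is symmetric
under a label flip, so audio-trained accuracy equals video-trained
accuracy.  `mcgurk_dual_decoding` therefore trains one classifier per
pair on the percept-defining video identity and scores the *same
predictions* against both labelings — producing mirror-image accuracies
(video above, audio below 50%), the construction that makes a decoder
"consistently choose the wrong" audio identity.

## Information tendency

From each electrode's confusion table, p(r|s) = counts(s,r)/counts(s,·).
The joint over (S, R_x, R_y) is assembled as p(s)·p(r_x|s)·p(r_y|s) —
conditional independence of the two electrodes' decoded responses given
the stimulus, the only construction available from per-electrode
tables; the stimulus prior defaults to empirical frequencies.  The
conditional mutual information

    I(S;R_x|R_y) = Σ p(s,x,y) log₂ [ p(s,x|y) / (p(s|y) p(x|y)) ]

uses base-2 logarithms (bits), the 0·log 0 ≡ 0 convention and no
pseudocounts (optional additive smoothing exists for very small n).
The **information tendency** I(S;R_x|R_y) − I(S;R_y|R_x) is the net
transfer from electrode Y to X; with edges ordered caudal-first
(posterior→middle, middle→anterior), positive means caudal→rostral.
By the chain rule this difference equals I(S;R_x) − I(S;R_y), a useful
sanity check: the statistic asks which electrode's response carries
more stimulus information.

**Interval analysis** recomputes features and confusions independently
for three one-second intervals — baseline [−2,−1], video-only [−1,0],
audio+video [0,1] — restricting voltage samples to the interval and
spectrogram windows to full support inside it (no cross-interval
leakage).  Trials pool all behavioral categories except unclassified.
The per-edge tendency is the mean over syllable pairs; per-pair values
are retained as replicates.

**Null band.**  The hypothesis "no net transfer" makes the two
electrodes of an edge exchangeable, which flips every per-pair
tendency's sign.  The null distribution of the mean tendency is
therefore built by random sign flips of the per-pair values
(`signflip_null_tendencies`).  A stimulus-label permutation is *not*
used here: it destroys all stimulus information and so understates the
tendency's estimation noise whenever the electrodes are informative —
it remains the correct null for decoding accuracy itself
(`permutation_null_tendencies` and the chance-calibration check).
When several tendencies are screened at once, a simultaneous
(max-statistic) band across the family controls the joint error rate.

## Statistics

Behavioral accuracy: one-way ANOVA over per-trial correctness by
category plus Tukey-Kramer pairwise comparisons (unequal group sizes).
Difference statistics: two-sided Mann-Whitney U (exact for small
untied samples).  Decoding accuracies: one-sample two-sided Wilcoxon
signed-rank against the 50% chance median, zeros dropped, degenerate
all-at-chance input reported as p = 1.  All tests are two-sided by
default; type-I calibration at α = 0.05 is part of the acceptance
suite.

## Problem sizes and determinism

Default conditions: 8 electrodes (3 coding), 10 trials per combination
(160 trials, comparable to one subject's session), 1 kHz sampling,
3.5 s epochs.  Property checks use 20 independent seeds for
recovery/null claims, 100 label permutations for chance calibration,
1000 random joints for the estimator-oracle bound and 500 replicates
per hypothesis-test calibration.  Every stochastic step takes an
explicit seed; identical configurations produce bit-identical datasets
and artifacts (HDF5 written without object timestamps).

## Known limitations

* The conditional-independence construction ignores trial-by-trial
  response correlations between electrodes; pairing per-trial
  predictions would need the joint confusion table, which the
  per-electrode construction deliberately avoids.  The plug-in CMI is
  biased upward at small trial counts (quantified by the convergence
  test); tendencies subtract two equally-biased terms, which cancels
  most of it.
* The tendency is an information *asymmetry*, not a causal flow
  estimate; a third source driving both electrodes at different
  strengths produces the same signature.
* Interval-restricted spectrogram features require full window support,
  so each interval contributes only ~0.5 s of window centers; very
  short intervals (< one window) would yield voltage-only features.
* With ≤2 trials per combination the behavioral rule cannot label any
  incongruent combination, leaving everything unclassified.
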