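# Methods

## Overview

`lonespeech` implements a speech-based assessment of loneliness in older
adults: each participant answers eight daily-life questions; every response
(audio + transcript) is reduced to acoustic, prosodic and linguistic
features; the resulting 160-dimensional session vector is screened against
the UCLA Loneliness Scale total score (20–80, higher = lonelier) and fed to
cross-validated regression and binary-classification models.  Because the
original recordings are not public, the package ships a synthetic-cohort
generator that emulates the study conditions end-to-end, so every stage is
exercised against data with known ground truth.

## Feature extraction

**Voice activity detection.**  Responses are resampled to 16 kHz and split
into voice/silence segments by frame energy: non-overlapping 25 ms frames,
a frame is voice when its RMS exceeds the loudest frame by more than
−30 dB.  Label runs shorter than 0.2 s are absorbed in two passes (silences
bridged first, then isolated voice bursts dropped) so the segmentation does
not flicker at phone rate.  The original study segmented audio with a cloud
ASR service; an energy-based detector was chosen here because it is
deterministic, dependency-free and testable.

**MFCC / ΔMFCC variances (14 per response).**  Hann-windowed 25 ms frames
(10 ms hop) fully inside voice segments; 512-point FFT power spectrum; 26
triangular mel filters spanning 0–8 kHz; orthonormal DCT-II of the log
filterbank energies.  Coefficients 1–14 are kept — the 0th coefficient is
overall loudness, not spectral shape, and is excluded by default
(`mfcc_include_c0` switches the alternative).  First-order deltas use the
standard regression formula with a ±2-frame window and replicated edges;
the per-coefficient population variance across frames is the feature.  Low
variance corresponds to monotone, spectrally static speech.

**Formants F1/F2.**  Per 30 ms voiced frame: mild pre-emphasis (0.97 is
conventional for natural speech, but the package default is 0.5 — impulse
excitation such as the synthetic cohort's glottal source already has a flat
spectrum, and heavier pre-emphasis biases low F1 estimates upward by
~15–20%), Hamming window, LPC order 2 + rate/1000 (= 18 at 16 kHz) fitted
by the autocorrelation method (Levinson–Durbin).  Polynomial roots in the
upper half-plane become (frequency, bandwidth) candidates, gated to
90–4000 Hz and bandwidth < 400 Hz; the first two survivors are the frame's
F1/F2 and the response value is the median over frames with ≥ 2 survivors.
Recovery error on source-filter synthesized vowels is ≲ 1% (median) across
F1 ∈ 300–800 Hz, F2 ∈ 900–2400 Hz.

**F0 and pitch variation.**  Normalized autocorrelation over 40 ms frames;
the search band is 60–400 Hz; a frame is voiced when the peak exceeds 0.6.
Subharmonics of periodic frames score nearly as high as the true period, so
among local maxima within 0.05 of the global peak the smallest lag wins
(standard octave-error guard).  Pitch variation is the population SD of F0
over voiced frames — the study never defines "pitch variation"
operationally; the SD convention is declared here and used throughout.

**Pause duration.**  Sum of silence intervals strictly between the first
and last voice interval.  Leading/trailing silence is excluded: it reflects
the recording window, not hesitation.  (Total vs. mean pause was also left
open by the study; total internal silence is the package convention.)

**Linguistic features.**  Tokenization is pluggable; the default splits on
whitespace and lowercases, which is exact for the synthetic language.  A
TSV lexicon assigns word polarity; positive/negative occurrences are
counted on the four sentiment-eliciting questions (childhood activity,
earthquake plan, travel plan, traditional event — questions 3, 6, 7, 8 of
the eight-question session), and the filler proportion is computed on all
eight (empty transcript ⇒ 0, keeping the vector total).  Negative-word
counts are retained as features even though no negative-word effect is
part of the generator: the feature definition includes them.

This yields (2 + 14) × 8 = 128 acoustic, 2 × 8 = 16 prosodic and
2 × 4 + 1 × 8 = 16 linguistic features = 160 per participant, with stable
names (`ac.f1.q3`, `pr.pause.q7`, `li.filler.q2`, …).  Responses whose
acoustics cannot be resolved are stored as NaN and median-imputed within
each training fold at modeling time.

## Correlation screening

Every feature is tested with Spearman's rank correlation against the UCLA
score; p-values use the t approximation t = ρ√((n−2)/(1−ρ²)), adequate at
n = 57 (an exact permutation mode exists for n ≤ 10).  Screening is
deliberately unadjusted for multiplicity at α = 0.05, matching the
exploratory protocol; a Benjamini–Hochberg option exists but is off by
default.  Age/sex control is rank-based partial correlation: feature,
score and confounders are all rank-transformed, feature and score ranks
are residualized on an intercept + confounder ranks, and the residuals are
correlated (t test on n − 2 − k df); this matches `pingouin`'s partial
Spearman to machine precision.  Post-hoc power uses the Fisher-z normal
approximation Φ(|atanh ρ|·√(n−3) − z_{1−α/2}); at n = 57 and α = 0.05, an
effect at the top of the observed band (|ρ| = 0.41) has power ≈ 0.89 while
the bottom (0.26) has ≈ 0.50 — only the strongest single feature clears
0.8, so non-significant screens at this sample size are inconclusive.

## Model evaluation

The high-loneliness class is defined by the cutoff round(mean + 1·SD) of
the cohort's scores (sample SD, half-up rounding; 37.0 + 8.6 → 46).
Models are evaluated with iterated (default 20×) 10-fold cross-validation,
stratified for classification.  Within every training fold — and only
there — features are median-imputed and z-scored, the 16 acoustic features
with largest training-|ρ| are pre-selected (with the 16 prosodic + 16
linguistic features this forms the fixed 48-candidate set), sequential
forward selection (SFS) picks the model inputs by inner 3-fold CV score
(R² / accuracy; ties break alphabetically; stop at no improvement or 12
features), and an optional grid search tunes hyperparameters on the
training split.  Metrics are computed per iteration over the pooled
out-of-fold predictions; reports carry the mean and a 95% t-interval over
iterations, pooled confusion counts (averaged over iterations, hence
fractional), per-fold selected features, and optional per-sex metrics.

Model families are kNN, random forest and RBF-SVM.  SFS re-fits the model
hundreds of times per fold, which is prohibitive for forests; when the
final family is a random forest the selection objective is an RBF-SVM
(`selection_family` overrides this).  EV is defined as
1 − Var(y−ŷ)/Var(y), which coincides with R² only for unbiased
predictions.  Grid defaults: k ∈ {3,5,7}; trees ∈ {100,300} × depth
∈ {3,5,none}; SVM C ∈ {1,3,10}, RBF width at the scale heuristic,
ε ∈ {0.5,1,2} (regression) and class weights ∈ {none, balanced}
(classification).  The searched parameters follow the protocol; the ranges
are package defaults chosen once for n ≈ 50 cohorts.

## Synthetic cohort

The generator emulates: 57 participants, integer UCLA scores from
Normal(37.0, 8.6) truncated to [20, 80]; ages uniform on 62–81; balanced
sex.  Six latent voice parameters carry monotone loneliness links with the
directions reported for real speech — pitch variation (−), pause (+),
F2 (−), spectral dynamism/ΔMFCC variance (−), positive words (−),
fillers (+).  Each link is a Gaussian slope calibrated (bivariate-normal
rank inversion + pilot verification) to a target Spearman |ρ|, defaulting
to the midpoint of the reported significant band (0.26–0.41).  Two
deliberate exceptions: the count-valued linguistic families use the band's
upper end, because i.i.d. token draws attenuate a count's correlation
below its latent rate's correlation, and the link noise is orthogonalized
to the realized score vector (conditional simulation), so the in-sample
latent correlation equals the calibrated slope exactly — the band the
generator must reproduce is defined at the cohort size, not merely in
expectation, and at n = 57 an unconditional draw misses it by ±0.13
routinely.

Audio is source-filter synthesis: a glottal impulse train whose F0 is
redrawn every 100 ms from Normal(f0_mean, f0_sd), passed chunk-wise
through resonators near 550 Hz and the participant's F2, with silence gaps
summing to the pause total and a noise floor 35 dB below speech RMS.
ΔMFCC-variance effects are driven by chunk-wise wander of the resonator
frequencies plus amplitude modulation, with depth tied to the latent.
Pure amplitude modulation alone would not work: a uniform gain scales all
mel energies equally, which the log maps to an additive constant absorbed
entirely by the excluded c0.  Driving the effect through the spectral
envelope means it must survive the real extraction chain, which is the
stronger test.  Transcripts are i.i.d. token draws (filler / positive /
negative / neutral pseudo-word) at ~4 tokens per voiced second from a
bundled toy lexicon, exact under the default tokenizer.

What the generator does **not** emulate: phones, prosodic phrasing,
coarticulation, speaker timbre, recording-channel effects, ASR errors, or
any multivariate structure beyond the six independent latents.  Passing
tests therefore show that the pipeline recovers planted monotone effects
of realistic size through a realistic signal chain — not that the specific
performance numbers transfer to real recordings.

### Attainable model performance on the synthetic cohort

With six mutually independent latents each at |ρ| ≈ 0.335, the population
R² of the best joint predictor is ≈ 0.43, and the cross-validated R² of an
oracle given the *true latent parameters* at n = 57 is only ≈ 0.22–0.26.
Extraction noise and fold-wise feature selection sit below that ceiling:
under the full protocol the combined feature set lands near R² ≈ 0, and
the single-type sets land clearly below it.  This is a property of the
study conditions (band-calibrated independent effects at n = 57, where
SFS over 48 weak candidates pays a winner's-curse penalty), not of the
implementation: the same protocol recovers R² > 0.2 when a stronger
multivariate signal is planted (see the tabular protocol tests), and the
no-leakage control stays ≤ 0.05 under permuted targets.  The qualitative
input-set ordering — combined features beating the single-type sets — is
reproduced and asserted; the original study's absolute performance levels
are not reproducible from marginal effect sizes alone and are not asserted
anywhere.

Default problem sizes for the bundled analyses: responses of 4–12 s
(sentiment questions 8–12 s) at 16 kHz, 10 CV iterations for cohort-level
model evaluation, 300-tree forests with the grid search disabled (the
fold-wise grid adds selection noise at n = 57 and multiplies cost).  A
`--realistic-durations` flag restores the study's 4.2–75.4 s response
range, and `RunConfig.cv_iterations = 20` restores the full protocol.

## Numerical conventions

- All frame-level aggregations use population (ddof = 0) variance/SD; the
  cutoff rule uses sample (ddof = 1) SD; both declared once.
- Cutoff rounding is half-up (`floor(x + 0.5)`), so 45.6 → 46.
- SFS and grid-search ties break to the alphabetically/first-listed
  candidate; all CV shuffles derive from the run seed; reports are
  bit-identical across runs with the same seed.
- Constant feature columns screen as ρ = 0, p = 1 instead of aborting.
- A variable explained near-exactly by the confounders (rank-residual norm
  < 1e-8 of its centered norm) reports partial ρ = 0.
- Degenerate audio (all zeros, frame longer than the signal, no voiced
  frames) raises immediately with a named reason.

## Known limitations

- The energy-based VAD assumes a quiet recording environment (as in the
  study's setup); it has no noise robustness.
- Formant tracking by LPC root-gating can lose F1 below ~250 Hz or merge
  closely spaced formants; the synthetic vowels avoid these regimes and
  real-speech use should treat per-frame values with care.
- The classification task is heavily imbalanced (≈ 10 of 57 positive); at
  desk scale the balanced-weight SVM trades accuracy for sensitivity, and
  fold-wise metrics are noisy.
- Spearman screening at n = 57 is underpowered for most of the observed
  band (see post-hoc power above); flagged-set membership is unstable
  under resampling.
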