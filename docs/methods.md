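# Methods

`sepsisfuse` implements a two-stage system for early sepsis-onset risk
prediction: a hardware-constrained classifier that runs on continuous
single-lead ECG, and a cloud-side fusion stage that combines the ECG
model's scores with an EMR (demographics + comorbidity text) classifier
through a stacked meta-learner, evaluated separately for each prediction
horizon before onset.  Because the clinical waveform/EMR data such a
system would train on is not publicly available, the package ships a
synthetic cohort generator whose programmable effect sizes make every
stage testable end to end.

## Synthetic cohort generator

### What it emulates

Each patient gets a single-lead ECG record (300 Hz, 8 h by default), a
binary sepsis label with an onset timestamp, demographics (age bin,
gender, race, ethnicity) drawn from configurable group proportions, and a
comorbidity history as ICD-10-style free-text phrases.  The default class
balance is 53.3% sepsis and the default demographic marginals describe a
mixed urban ICU population that skews elderly.

The waveform is a sum of per-beat PQRST templates — five Gaussian bumps
per beat — placed at R-R intervals drawn from a Gaussian with the
patient's current mean heart rate and heart-rate-variability SD, plus:

* respiratory amplitude modulation (±8% at 0.25 Hz),
* slow baseline wander (±0.05 amplitude units at 0.3 Hz),
* per-beat multiplicative amplitude jitter (SD 5%),
* additive white noise (SD 0.02 against a unit R amplitude).

These shared realism terms exist so that the R-peak threshold genuinely
matters: with perfectly uniform beat amplitudes any threshold between the
noise floor and the R amplitude would behave identically, and the
threshold sensitivity the detection stage is supposed to exhibit would be
untestable.  The P wave (R−160 ms) and T wave (R+180 ms) deliberately sit
inside the detector's 200 ms refractory neighbourhood of the much larger
R wave, so a correctly configured detector reports exactly one peak per
beat.

The sepsis signature follows the electrophysiological picture of
sepsis — tachycardia, depressed heart-rate variability, and prolonged,
lower-amplitude QRS complexes: at full effect the heart rate is elevated
by `hr_sepsis_delta_bpm` (default +30 bpm), the R-R SD is multiplied by
`hrv_sepsis_scale` (default 0.5), and the Q/R/S bump widths and
amplitudes are scaled by `qrs_width_scale` (default 1.3) and
`qrs_amp_scale` (default 0.7).  All four effects ramp linearly from zero
to full over `ramp_hours` before the assigned onset and stay at full
afterwards.  The linear ramp is a modelling choice, not a physiological
claim: nothing reliable is known about how far before onset ECG
morphology begins to drift, and the ramp's one virtue is that it makes
per-horizon difficulty monotone by construction, which is the qualitative
property the horizon analysis needs.  Onset times are drawn uniformly
over the interval that leaves every configured horizon plus a block of
analysis windows inside the record.

Every record carries a ground-truth R-peak channel defined as the local
argmax of the noise-free waveform at each placed beat (the rounded beat
time is snapped within ±2 samples), so detection and feature recovery can
be scored exactly.

EMR text is sampled without replacement from a bundled synthetic
dictionary of 24 ICD-10-style disease descriptions, 1–5 phrases per
patient.  Eight phrases form a designated risk subset whose sampling odds
are multiplied (default ×3) for sepsis patients.  This injects a weak but
learnable class signal into the text — deliberately weak, because in this
problem comorbidity history alone is a mediocre sepsis predictor and the
fusion analysis is only interesting if the EMR channel is informative but
insufficient.

All generator outputs are pure functions of the configuration and its
seed; per-patient, per-stage substreams are derived from the master seed
so any single patient's ECG or EMR can be regenerated independently.

### What it does not emulate

Real 12-lead morphology, arrhythmias, artefacts (electrode motion, muscle
noise), non-stationary circadian structure, correlations between
demographics and physiology, and clinical adjudication of onset (onset is
assigned directly, not derived from organ-dysfunction scoring).  Passing
tests on this cohort therefore demonstrate that the pipeline's machinery
is correct and recovers programmed effects — not that the learned models
would transfer to clinical data.

### Desk scaling

Full-length generation (8 h records, hourly horizons) is available but
slow to iterate on, so tests, examples and the acceptance analysis run a
desk-scale configuration: 0.5 h records with the horizon unit shrunk from
3600 s to 180 s and the effect ramp from 6 h to 0.3 h.  This preserves
the six-step horizon structure and the ramp geometry — every horizon sees
the same ramp fraction as its full-scale counterpart — at 1/20 of the
compute.  `CohortConfig.desk_scale()` constructs it.

## ECG pre-processing and features

Each record is cut into non-overlapping 9000-sample windows (30 s at
300 Hz; both window length and stride are configurable).  Each window is
min-max normalized to [0, 1] and then baseline-corrected by subtracting
its median; constant windows are skipped with a warning.  R peaks are the
local maxima above `min + 0.30 × (max − min)` of the corrected window,
post-filtered by a 200 ms refractory rule that keeps the largest
candidate in each neighbourhood (earliest index on ties).  Candidates
within one refractory distance of the window edge are deferred to the
neighbouring window, since their neighbourhood is truncated.  The 30%
threshold and the thresholding-on-the-corrected-signal convention are the
defaults the rest of the package assumes; the threshold is exposed
because accuracy degrades on both sides of it (too low picks up noise and
wander maxima, too high loses low-amplitude beats under respiratory
modulation).

Fourteen time-domain features are computed per window — deliberately
time-domain only, since the intended host is a low-power on-sensor
feature extractor for which frequency transforms are disproportionately
expensive:

| group | features |
|---|---|
| amplitude distribution | mean, median, mode, SD, variance, skewness, kurtosis |
| R peaks | count, mean amplitude, amplitude variance |
| R-R intervals | mean (s), SD (s), RMSSD (s) |
| rate | mean heart rate (bpm) |

Conventions: population (uncorrected) moments; Fisher kurtosis (normal →
0); the mode is the midpoint of the fullest of 16 equal-width histogram
bins over the pre-correction [0, 1] signal (lowest bin on ties); R-R
intervals are `diff(peaks)/fs`; heart rate is `60 × (count − 1) /
elapsed` between first and last peak.  Windows with fewer than two peaks
get zero rate features and a sparse-peaks flag; R-R dispersion features
need at least three peaks.

Per-horizon datasets take, for each sepsis patient, the `k` consecutive
windows (default 10) ending `h` horizon units before onset.  Non-sepsis
patients contribute `k` windows placed by the same rule against a
pseudo-onset at `record_end − 30 s`, so negative windows shift with the
horizon exactly as positives do and window position cannot leak the
label.

## The analog classifier and error-aware training

The deployed classifier is a dense 14-20-6-1 network realized in analog
hardware, and the simulator reproduces its three non-idealities:

1. **Input quantization.** Features are min-max scaled to [0, 1] with
   statistics from the training rows (the DAC input range is fixed
   hardware, so test-time values clip), then rounded half-up to the
   nearest of 16 levels `k/15` (4-bit DACs; bit depth configurable).
   Quantization error is bounded by half an LSB, `1/30` at 4 bits.
2. **Charge-sharing MACs.** Each neuron's weighted sum is computed by
   passive charge redistribution over the weight capacitors, which
   physically yields the capacitance-normalized sum
   `z = (Σ wᵢxᵢ + b) / (Σ|wᵢ| + |b|)` — the faithful abstraction of why
   the hardware's pre-activations are intrinsically bounded to [−1, 1]
   (the simulator asserts this bound on every forward pass).  Weights
   stay continuous: they are capacitor ratios, not digital codes.
3. **Amplifier activations.** The tanh/sigmoid stages are five-transistor
   amplifiers whose transfer curves only approximate the mathematical
   functions.  The simulator represents each as a 257-point monotone
   lookup table over [−1, 1] with linear interpolation, built from a
   parametric family `sat_lo + (sat_hi − sat_lo)·(tanh(gain·(x+offset))+1)/2`
   (logistic analogue for the sigmoid kind) with optional per-instance
   input-referred offset mismatch.  The parametric family is this
   package's characterization of such an amplifier; a user with measured
   transfer curves can load them directly as tables.

**Error-aware co-design.**  Training runs mini-batch SGD with binary
cross-entropy where the forward pass is the full analog path and the
backward pass uses straight-through quantization and the lookup table's
piecewise-linear derivative.  Gradients therefore flow through the same
non-idealities inference will see, and the trained weights absorb them —
the alternative (train ideal, deploy analog) leaves an accuracy gap that
this procedure is designed to close.  An `ideal` mode (exact affine
pre-activations, exact tanh/sigmoid) provides the mathematical reference;
with the ideal surrogate it reproduces a textbook backprop trajectory,
which is how the trainer is validated.

Splits are at the patient level (default 80/20), never at the window
level, so windows of one patient cannot straddle the partition.  Plain
SGD with a fixed learning rate is the default optimizer; everything is
deterministic given the seed.

## EMR model

Demographic columns are integer-coded against a codebook of sorted unique
training values (unseen test values get a reserved code with a warning).
Comorbidity phrases are joined into one document per patient, lowercased,
stripped of non-alphanumeric characters and whitespace-tokenized.  TF-IDF
uses: term frequency normalized by document length; inverse document
frequency `ln(N/DF)` with no smoothing (vocabulary terms have DF ≥ 1 by
construction, and a term present in every document gets weight exactly
0); and a vocabulary of the top-20 terms by document frequency with
lexicographic tie-breaking.  The TF-IDF block is concatenated with the
encoded demographics and standardized column-wise with training-row
statistics (population SD; constant columns left at zero).

Five classifier families are available behind one interface — linear SVM
(margins mapped through a logistic link to [0, 1]), logistic regression,
random forest (the default), gradient boosting, and a two-hidden-layer
MLP — with hyperparameters selected by 10-fold cross-validated accuracy
over small fixed grids (the fold count degrades gracefully when the
minority class is smaller than the fold count).

## Late fusion and evaluation

The ECG model's window scores are aggregated to one score per patient per
horizon (mean by default; max and last are available).  The EMR score is
horizon-independent and repeated across horizons.  A meta-learner (same
classifier suite) is trained per horizon on the two-column score table;
*setting 1* pairs the ECG score with a demographics-only EMR model,
*setting 2* with the demographics + comorbidity model.  One patient-level
80/20 split drives the whole stack: ECG models, EMR models and
meta-learners all fit on the training side, and every reported metric
comes from the held-out side.  There is no stacking-specific inner
split: the meta-learner sees the base models' scores on the same
patients those models trained on.  This never contaminates held-out
metrics, but it does mean the meta-learner can overweight a base model
whose training scores are overconfident (tree ensembles with near-zero
training error are the usual culprit), visibly so on small cohorts; the
effect shrinks with cohort size.  Out-of-fold score stacking would
remove it at the cost of refitting every base model per fold.

Evaluation reports confusion counts at a 0.5 score threshold, accuracy,
sensitivity, specificity, and AUROC computed by the rank (pairwise
concordance) definition with ties counted ½.  Degenerate held-out sets
(one class absent) yield explicit nulls rather than numbers.

**Fairness audit.**  For each demographic attribute, each subgroup's
false-positive rate — false positives among the group's labelled
negatives — is divided by the reference group's; ratios inside
[0.8, 1.25] are flagged fair, following the 80% rule for disparate
impact.  The false-negative analogue is available via `rate="fnr"`.
Groups with fewer than 10 eligible members are reported but marked
`insufficient_n`.  On the synthetic cohort demographics are independent
of physiology, so disparities beyond sampling noise indicate a pipeline
defect; on real data this audit is diagnostic, not corrective.

## Numerical and design choices

* Local maxima are indices strictly above the previous sample and at
  least as high as the next (flat-plateau peaks resolve to their first
  index); refractory conflicts resolve largest-first, earliest on ties.
* DAC rounding is deterministic half-up; saturations are counted in a
  log rather than raised.
* The degenerate-input policy is: constant windows are skipped upstream;
  empty documents contribute zero TF-IDF vectors; all-zero neuron weights
  are an error (the charge-sharing denominator would vanish); single-class
  training sets are an error everywhere.
* Determinism: every stage derives its randomness from a named substream
  of the master seed; no stage reads OS entropy.  Two runs from the same
  seed produce byte-identical metric tables.

## Problem sizes used by the shipped analyses

The test suite and the acceptance analysis run the desk-scale cohort
(0.5 h records, 180 s horizon unit) with 500 patients for effect-recovery
and study-shape checks and 10–120 patients for unit and integration
checks; the analog network trains for 60 epochs there.  These sizes are
the package's chosen demonstration conditions; the generator and pipeline
accept full-scale settings unchanged.

## Known limitations

* The amplifier transfer family is parametric, not circuit-measured; the
  simulator's analog/ideal gap therefore reflects the family's shape, not
  a specific silicon implementation.
* The Gaussian-bump ECG model carries no rhythm pathology; the feature
  roster was chosen for the synthetic signal's information content and
  covers the standard first-order time-domain HRV set, but its exact
  composition is a design decision.
* The fusion analysis assumes both modalities are available for every
  patient; missing-modality handling is out of scope.
* Energy, area and transistor-level behaviour of the hardware are out of
  scope; the simulator models information flow, not physics.
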