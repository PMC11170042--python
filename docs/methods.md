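# Methods

This note documents the models, conventions and defaults behind the
pipeline, the synthetic-cohort generator it is validated against, and the
limits of what those validations show.

## Measurement model

### MSDA (activity)

The activity metric is the sample standard deviation (denominator n−1) of
the Euclidean norm of the tri-axial acceleration over consecutive,
non-overlapping 2-s windows aligned to the session start. Choices worth
stating:

* **Norm, not per-axis.** The norm makes the metric invariant to strap
  orientation on the chest; subtracting the window mean removes the
  gravity offset, so MSDA responds only to movement. The documented
  invariances (offset along the signal direction; linear scaling) are
  property-tested.
* **Non-overlapping aligned windows** keep daily totals additive and make
  the training/nontraining decomposition exact: a window belongs to the
  training period iff its *start* lies in a training interval, so
  `msda_total = msda_training + msda_nontraining` holds identically.
* **Gaps poison windows.** Any window intersecting a declared gap is
  dropped, never zero-filled.
* Daily totals are sums of window values, in g-units; the scaling of
  published daily totals on any particular device firmware is not
  knowable, so a calibration constant is left to the user (default 1).

### Posture

Per 5-s epoch the gravity direction is estimated as the per-axis median of
the epoch's samples (computed on a decimated subset, ~25 samples per
epoch — gravity varies slowly, and the median is robust to movement
bursts). An epoch is *lying* when the angle between gravity and the
device's longitudinal (trunk) axis exceeds θ = 50° from vertical,
configurable; upright otherwise. Epochs with under 50% of nominal samples
become *gap*. Epochs therefore tile the session exactly, which is what
makes the daily minutes ledger (lying + sitting/standing + walking + gap =
1440) exact.

Upright epochs are refined to *walking* when (a) the epoch's mean MSDA is
at least 0.05 g and (b) the dominant spectral peak of the mean-removed norm
lies in the 1–3 Hz cadence band **and** carries ≥ 20% of the epoch's AC
power. The concentration requirement is deliberate: broadband fidgeting
can exceed the activity threshold, and the argmax bin of white noise lands
in the cadence band by chance roughly one time in six, which would
systematically inflate walking minutes; requiring a concentrated peak
rejects that failure mode while a genuine cadence line (which puts most of
its power in one bin) passes easily. The walking rule as a whole is a
design choice — published figures report walking minutes without
disclosing a classifier.

### Heart-rate anchors and %HRR

* **Resting HR** = median of heart-rate samples that are simultaneously
  inside the 00:00–05:00 clock window and inside lying-labeled epochs,
  pooled over both nights of a 48-h session (one anchor per session). If
  fewer than 30 min of such samples exist the pipeline fails loudly,
  naming the patient-session; there is no silent fallback.
* **Max HR** = measured value when present, else 220 − age (the classical
  guideline formula); Tanaka's 208 − 0.7·age is available by
  configuration.
* **%HRR** is the pointwise affine transform
  100·(HR − HR_rest)/(HR_max − HR_rest). Sub-resting values remain
  negative (they are informative), values above 100 are kept. Daily and
  period means are unweighted sample means, which at a uniform 1 Hz makes
  the overall mean exactly the duration-weighted combination of period
  means (checked to 1e-9 relative).

### Days and periods

Days are local calendar days [00:00, 24:00); partial leading/trailing
slices are flagged and excluded from cohort means by default (a 48-h wear
can straddle three calendar days). Sleep is included in the nontraining
period. The device swap at the 24-h mark is a zero-duration schedule
marker by default (configurable as a real gap); bathing is a true gap.

## Statistics

* **Wilcoxon signed-rank** (0W vs 4W, two-sided): zero differences
  discarded (classical convention; Pratt available), mid-ranks for tied
  |d|, statistic W = min(W+, W−). For n ≤ 15 the p-value is exact by full
  enumeration of the 2^n sign assignments (valid under ties); beyond that,
  normal approximation with tie-corrected variance and continuity
  correction. The two-sided p doubles the smaller tail, clipped at 1. The
  exact test is conservative at small n because the null is discrete: at
  n = 11 the achievable size near 0.05 is below nominal, which the
  calibration test's acceptance band [0.03, 0.07] anticipates.
* **Spearman ρ**: Pearson correlation of mid-ranks. Default p from the t
  approximation with n − 2 df; a seeded Monte-Carlo permutation p
  (add-one corrected) is available and recommended at n ≤ 15. Exact
  enumeration of 11! permutations is deliberately out of scope.
* α = 0.05 per test, two-sided, no multiplicity correction by default
  (Holm is provided but off), mirroring the small-cohort reporting
  convention this pipeline targets.

## Synthetic cohort generator

The generator emulates the study conditions: 11 patients, two sessions
(admission and 4 weeks), 48 h each, 25 Hz acceleration, 1 Hz heart rate,
≈3 h of scheduled training per day, one bathing gap per day, a device swap
at 24 h. The ward timetable (night 21:00–06:00, training blocks at 09:30
and 14:00, bathing 18:00) is invented — no published timetable exists —
and configurable. The 180 min/day training default is an inference: with
training at ≈22% HRR and nontraining at ≈9.5%, a ≈1/8 share of the day in
training is what makes a ≈11% 24-h mean arithmetically consistent.

* **Acceleration** = posture-dependent gravity unit vector (trunk axis
  vertical when upright, horizontal when lying) + iid Gaussian noise with
  the interval's configured SD (lying 0.01 g, sitting/standing 0.03 g,
  training 0.06 g, walking 0.10 g), plus a 0.25 g sinusoid at the 2 Hz
  cadence while walking. The recorded per-interval truth is the SD of the
  resulting norm (for walking, √(σ² + a²/2)).
* **Heart rate** = HR_rest + f(t)·(HR_max − HR_rest), f(t) an AR(1)
  process (correlation time 30 s) around per-interval means. Lying
  intervals carry a true %HRR of 0: resting HR is *defined* downstream as
  the night lying median, so the recoverable intensity process must be at
  its resting anchor during that window; the daytime nontraining level is
  then solved from interval durations so the nontraining period mean hits
  its target (9.47% by default), or so the whole-day mean hits
  `hrr_total_target` when set. The AR(1) stationary SD is 0.02 (fraction
  of HRR), chosen so an interval-mean over 1 h has standard error ≈0.26%
  and the generator's stated calibration guarantee (interval means within
  1% absolute at ≥ 1 h) holds with ≈4σ margin.
* **Cohort structure**: per patient-session multipliers scale training
  noise up with the FIM motor z-score (slope 0.45) and nontraining noise
  down with the age z-score (slope 0.45), with multiplicative Gaussian
  noise (SD 0.12) so realized rank correlations are strong but not
  degenerate. Zero slopes give a null cohort.
* **Determinism**: all randomness flows from the config seed through
  named substreams (one per patient-session), so identical configs are
  bit-identical and adding patients does not perturb earlier ones.

### What the generator does *not* emulate

Real electrode artifacts, Bluetooth dropouts, beat-detection errors,
postural transitions slower than one epoch, naps with elevated night HR,
arrhythmia, or any circadian drift of resting HR. Passing recovery tests
therefore demonstrates the pipeline's internal consistency — that each
stage measures what the upstream truth defines — not field accuracy on
hospital recordings.

## Validation harnesses and problem sizes

Recovery studies use single 24-h days at the full 25 Hz rate — the
calendar day is the unit every daily summary is defined on, and one day
per patient keeps the simulation studies at desk scale:

* **Intensity recovery**: 20 seeds × one day calibrated to the
  admission-phase mean (11.05% from the packaged calibration file); median
  recovered 24-h mean %HRR agrees within ±0.5 points. The residual error
  per seed is dominated by the night-median estimate of resting HR
  entering the %HRR denominator.
* **Structure recovery**: 20 seeds × 11 patients; median recovered
  ρ(training MSDA, FIM) ≥ +0.8 and ρ(nontraining MSDA, age) ≤ −0.6 under
  default couplings; |median ρ| ≤ 0.3 under the zero-coupling control.
* **Type-I calibration**: 2,000 null cohorts of n = 11.
* **Oracle equivalence**: MSDA vs two-pass SD (1e-12 relative), exact
  Wilcoxon vs sign enumeration for all n ≤ 10, Spearman vs the classical
  1 − 6Σd²/(n(n²−1)) closed form on tie-free data.

## Degenerate inputs and numerical conventions

Empty series yield empty results; a fully gapped day yields explicit
missing markers, never zeros; an empty training period yields
`msda_training = 0` but an *undefined* training %HRR mean; all-zero paired
differences yield a flagged degenerate test with p = 1; constant ranks
yield a flagged undefined ρ. Half-open interval convention `[start, end)`
throughout; window/period membership by start time; CSV round-trips are
value-exact (floats at full precision, timestamps at microsecond
resolution).

## Known limitations

* The posture classifier distinguishes lying from upright by a single
  trunk-angle threshold; reclined-but-awake postures land on whichever
  side of 50° they fall.
* Walking detection assumes a dominant cadence line; very slow or highly
  asymmetric gait with diffuse spectra may be under-detected — a
  conservative direction for a post-stroke cohort, and the reason MSDA
  rather than step counts is the primary activity metric.
* The %HRR intensity scale inherits the error of the age-predicted maximum
  heart rate when no measured value exists.
* Daily MSDA totals are in g-units; comparisons against device-scaled
  published totals require the calibration constant.
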