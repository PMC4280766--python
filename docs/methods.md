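# Methods

## Problem and data model

One *trial* is a single repetition of one of seven lower-limb
rehabilitation exercises, recorded by up to three IMUs (thigh, shin,
foot; tri-axial accelerometer in m/s², tri-axial gyroscope in deg/s,
102.4 Hz). Trials are pre-segmented: segmentation of continuous streams
is out of scope. A trial's label is either "correct" or a list of
observed error modes with 0–10 severities; the permitted error modes are
exercise-specific:

| exercise | permitted errors |
|---|---|
| heel slide | HeelLifts, HipER, JerkyMovement |
| hip abduction | HipER, KneeFlx, HipFlx |
| hip extension | HipER, KneeFlx, HipAbd |
| hip flexion | KneeFlx |
| knee extension | HipFlx |
| IRQ | HipFlx, HipER |
| SLR | KneeFlx |

Exercises with a single permitted error (hip flexion, knee extension,
SLR) are evaluated in binary mode only — detecting "incorrect" already
names the error. Raw-signal units are a package convention
(accelerometer m/s², gyroscope deg/s); conversion is the caller's
responsibility if other units are recorded.

The on-disk store is one CSV per trial plus a JSON manifest
(`sampling_rate_hz`, per-trial subject/exercise/repetition/file/label
records). Plain text keeps fixtures inspectable; round-tripping is exact
up to float-to-text precision (`%.9g`).

`trial_accounting` turns enrolment (58 subjects × 10 repetitions in the
emulated design) and explicit exclusion records into per-exercise trial
counts. With the design's recorded losses it yields 570 trials for heel
slide and the three standing exercises, 560 for knee extension and 550
for the SLR. The design's stated exclusions imply 580 IRQ trials; the
package reports only counts derivable from the records it is given and
does not fabricate an exclusion to match any other figure.

## Signal processing

Pitch/roll are accelerometer-only tilt estimates (atan2 conventions
above; degrees). Gyroscope-fused orientation is deliberately out of
scope: for slow rehabilitation movements the gravity component dominates
the accelerometer, and tilt is a sufficient orientation summary for
classification. The 20 Hz 4th-order Butterworth is applied
forward–backward (`filtfilt`): the analysis is offline, so zero phase is
free, at the cost of squaring the single-pass magnitude response (the
test oracle uses the squared, bilinear-prewarped response). Signals are
derived first and then all nine are filtered; a `filter_first` flag
swaps the order for sensitivity analyses but is not the default.

## Features

14 features per signal × 9 signals = 126 per sensor. Conventions are
fixed so golden values are stable:

* population (not sample) moments; skewness m₃/m₂^1.5 and Pearson
  kurtosis m₄/m₂², both defined as 0 when m₂ = 0;
* energy Σx²; range max−min; percentiles with linear interpolation;
* level crossing rate counts consecutive pairs strictly straddling the
  signal *mean* (gravity offsets make zero-crossings meaningless),
  divided by N−1;
* wavelet features are the variances of the Daubechies-5 detail
  coefficients at levels 6…2 of a level-6 decomposition under
  periodization. Level-1 details (≈25.6–51.2 Hz at 102.4 Hz) are
  omitted because the 20 Hz low-pass has already annihilated that band;
  this is the convention that makes the per-signal count 14 and the
  per-sensor block 126. Periodization is chosen because it makes the
  transform orthonormal on lengths divisible by 2⁶, giving an exactly
  testable Parseval identity; trials need ≥ 512 samples (5 s at
  102.4 Hz), and the generator snaps trial lengths to multiples of 64.

## Classification

Features are z-scored with training-fold statistics (zero-variance
features keep scale 1) and reduced by PCA on the standardized data —
equivalently, correlation-matrix PCA. Standardizing first is a design
choice the pipeline needs: the feature bank mixes scales that differ by
orders of magnitude (energy vs. skewness), so covariance PCA would be
dominated by a handful of energy features. The retained dimension k is
the smallest with cumulative explained variance ≥ 0.99.

Logistic regression is fit with a small ridge penalty, λ = 1e-4 by
default (λ = 0 allowed), for numerical stability on near-separable
folds; at this size the penalty shifts probabilities by far less than
any reported digit. The binary positive class is "incorrect" — the
clinically relevant event is a badly performed repetition, so
sensitivity is the detection rate of incorrect performance. Error
identification uses a one-vs-all bank with one logistic model per
surviving class **including "correct"** (a correct trial must be a
predictable outcome); the predicted class maximises the positive-class
probability, exact ties resolve to the class with the larger
training-fold prevalence and then lexicographically, making predictions
total and deterministic.

## Curation and evaluation

`resolve_class` keeps the largest-severity error (ties: taxonomy listing
order), `curate` drops unclassifiable trials and classes below
`min_examples` (default 40), logging every exclusion. The example floor
exists so that no class appears in a test fold that was unseen (or
nearly unseen) in training. Its granularity follows the task: for
multilabel evaluation each resolved class must clear the floor; for
binary-only evaluation the floor applies to the collapsed
{correct, incorrect} classes (`classes="binary"`), since the only
"unseen deviation" risk there is an absent incorrect class. At the
58-subject design scale the two coincide for the binary task; at desk
scale the distinction matters because a 3-error exercise splits its
incorrect trials three ways.

LOSOCV fits the projection and classifier per fold on the remaining
subjects only; folds whose training set loses a class (fewer than 2
examples) are skipped with a logged warning rather than silently merged.
Binary scores use positive = incorrect; multilabel sensitivity and
specificity are unweighted (macro) means of per-class recall and
per-class true-negative rate — the standard multi-class extension, fixed
here as a convention. Classes absent from the truths are excluded from
the macro averages with a warning.

The ablation report evaluates every exercise × 7 sensor subsets ×
applicable modes and adds a cross-exercise average row: an *unweighted*
mean over exercises, rendered as integer percent with half-up rounding
(62.5 → 63). Unweighted averaging plus half-up rounding is the unique
simple convention that reproduces the published average cells from the
published per-exercise cells, which the acceptance checks verify.
Full-precision floats are kept internally; rounding is display-only.

## Synthetic cohort generator

The generator is a study stand-in, not a biomechanical simulation. Each
repetition is a raised-cosine excursion of segment angles from a
posture-consistent rest position (standing, sitting or supine), with a
two-segment thigh/shin model plus foot. The accelerometer is gravity
(9.81 m/s²) projected through the site's pitch/roll series — so the tilt
formulas invert it exactly — and the gyroscope carries the angle
derivatives; segment translational acceleration is ignored except for
the heel-lift elevation transient, since tilt dominates slow
rehabilitation movements. Error modes superpose deviations whose
magnitude scales linearly with severity/10, at full severity: KneeFlx
40° shin/foot pitch deviation, HipFlx 25° thigh pitch, HipAbd 25° roll,
HipER 30° yaw with 30% coupled roll, HeelLifts 20° foot pitch plus an
8 cm elevation transient, JerkyMovement 5° of windowed 5/8 Hz
oscillation on the primary movement. Defaults: 60% correct prevalence
with the remainder split evenly over the exercise's errors (mirroring
the highly unbalanced clinical label distributions), severities uniform
on 1–10, noise SDs 0.3 m/s² and 1.5 deg/s (typical body-worn MEMS
magnitudes relative to these movements), 10% inter-subject
amplitude/duration variability (durations only lengthen, so the 512-
sample wavelet floor holds), 5 s nominal repetitions. Everything is a
pure function of the config including its seed.

What the generator does **not** emulate: soft-tissue artifact, sensor
misplacement, gyroscope drift, translational acceleration of segments,
within-repetition error onset/offset, correlated noise, or clinically
calibrated error magnitudes — the injection magnitudes are free
parameters chosen once, not estimates of patient data. Consequently,
passing synthetic tests demonstrates that the pipeline recovers known
structure without subject leakage; it does not certify clinical-grade
accuracy, and the published clinical efficacy tables are not
reproducible from synthetic data.

## Problem sizes and observed behaviour

The parameter-recovery study uses 20 subjects × 10 repetitions × 7
exercises with severity-10 errors (the package's desk-scale default for
self-checks). Under LOSOCV with all three sensors the binary classifier
recovers every exercise at ≥ 90% accuracy (saturating at 100% — at full
severity the injected deviations dwarf noise and subject variability,
by design); with a thigh sensor alone, exercises whose only error mode
lives on the shin or foot (hip flexion and SLR, both KneeFlx) drop
toward chance, which is the expected sensor-placement signature. A
permuted-label run on a balanced single-exercise cohort sits within
Monte-Carlo bounds of 50%, and accuracy is non-decreasing across
severities 2/6/10. The multilabel summary in the acceptance script uses
`min_examples=15`: at 200 trials per exercise, a three-way error split
cannot reach the 40-example floor arithmetically, so 15 is the
documented desk-scale threshold (the 40 default is kept for
design-scale data).

## Known limitations

* Tilt-only orientation: yaw-dominant errors are visible mainly through
  the gyroscope z channel.
* Euler-rate approximation in the generator's gyroscope (rates are
  per-angle derivatives, exact only for single-axis motion).
* The one-vs-all bank is uncalibrated; probabilities are used for
  argmax only.
* `rehab-imu evaluate` takes no seed: curation, LOSOCV and metrics are
  fully deterministic given the store.
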