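# Methods

This note documents the models, parameter choices and numerical conventions
behind `emgintent`, and what the synthetic-data results do and do not show
about recorded human EMG.

## Synthetic EMG generator

**Signal model.** Each channel is Gaussian white noise shaped by a 4th-order
Butterworth band-pass to 20–450 Hz (the standard surface-EMG acquisition
band), normalized to unit variance, then amplitude-modulated:

```
x_m(t) = [ b_m + A_m · e(t) + tonic_m ] · n_m(t)
```

where `b_m` is the baseline noise SD, `e(t)` a smoothstep burst envelope and
`A_m` the directional burst amplitude. Amplitudes are expressed on the
*recorded*-signal scale (the modeled acquisition chain amplifies
electrode-scale EMG by 1000×), so a ~120 µV burst appears as ~0.12 V; this
is the scale on which the 0.025 V zero-crossing threshold is meaningful.
With all gains zero a channel is pure baseline noise and its windowed mean
absolute value is the folded-normal mean `b·√(2/π)` — a generator
self-check in the tests.

**Directional tuning.** Muscle m firing toward direction θ:

```
A_m = g_m · max(0, cos(θ − θ_pref,m))^w + floor_m · g_m  (+ coupling terms)
```

Cosine tuning is the classical description of arm-muscle activation in
planar reaching; the rectified positive lobe with exponent `w = 2` (default)
keeps each muscle silent in its antagonist half-plane while sharpening the
agonist lobe. The seven-muscle healthy map places TR at 90° (North), DM/DP
near 0° (East), UT/BI near 270° (South) and PM/DA near 180° (West).
Defaults: `g = 0.12 V` (± per-muscle factors and ±10% per-subject jitter),
`b = 8 mV`, co-contraction floor 0.05. Seeds only jitter gains; the
preferred-direction map is the biology and is fixed.

**Timing.** Trials hold 400 ms of rest, the movement (1000/600/300 ms
protocol durations), and 300 ms of rest. The burst envelope rises from
50 ms *before* kinematic onset over 100 ms, holds through the movement and
decays over 150 ms; the 50 ms lead keeps the rising burst inside the
[−100, +100] ms analysis window while honoring the premise that EMG
precedes motion. Hand kinematics are a minimum-jerk path
`d·(10τ³ − 15τ⁴ + 6τ⁵)` of length 0.14 m (center-to-target; the target
radius is exposed as `target_distance` because descriptions of the target
circle are ambiguous between radius and diameter conventions). Minimum-jerk
peak speed is `1.875·d/T`, used as a closed-form oracle for the speed
pipeline.

**Stroke-like perturbations.** `make_stroke_subject(seed, severity)` scales
five abnormality axes linearly in `severity ∈ [0, 1]` (severity 0 is
exactly the healthy model):

* preferred-direction shifts, idiosyncratic per muscle, |shift| ∈
  [30°, 90°]·severity with random sign;
* co-contraction floor raised from 0.05 to 0.05 + 0.35·severity;
* agonist–antagonist synergy coupling for BI–TR and DP–DA with gain
  ≈ [0.6, 0.95]·severity, implemented as *shared drive*: the partner's
  tuned burst is injected with the partner's own noise carrier, so coupled
  channels are correlated and the coupling is visible to the covariance
  PCA (an amplitude-only coupling would leave channels independent, which
  PCA cannot detect and which is not what a synergy is);
* inter-trial per-channel lognormal gain variance with CV 0.5·severity
  (per-channel, because it is the spatial pattern's trial-to-trial
  instability that degrades pattern classifiers);
* tonic trunk drive 0.06 V·severity on trunk/shoulder-girdle channels.

A small always-on 5% per-channel gain jitter models electrode/skin
variability in all subjects.

**Protocols.** Healthy: 4 cardinal targets × 3 durations × 5 repetitions =
60 trials at 1000 Hz. Patient: 8 targets × 1 self-paced duration × 10
repetitions = 80 trials — the 10 repetitions read the 80-movement patient
session as two electrode blocks of 5 repetitions each, matching the
two-block recording procedure used when only 8 channels are available.

## Preprocessing

EMG: optional 20–450 Hz band-pass (only when the manifest marks the source
unfiltered — hardware-filtered data is not filtered twice), 10 Hz
Butterworth high-pass, and a 20 ms moving average of the rectified signal.
The signed (unrectified) high-passed signal is retained alongside the
envelope because zero crossings, signed histograms and the CoE covariance
need signed data. All Butterworth filters are order 4 and applied
forward–backward (`sosfiltfilt`), so group delay is zero and onset timing
is preserved (verified: detected onset moves ≤ 5 ms under filtering).

Kinematics: 15 Hz zero-phase Butterworth low-pass, central differences,
Euclidean norm → tangential speed. Onset is the first sample before the
global speed peak from which speed stays above 5% of the peak all the way
to the peak; requiring the crossing to lead monotonically into the peak
makes the rule robust to baseline noise (a plain "first crossing" can fire
on a noise blip long before the movement). Completion is the first
post-peak sample below threshold that stays below for ≥ 50 ms.

The analysis window is half-open, `[onset − 0.1·fs, onset + 0.1·fs)`, i.e.
exactly `0.2·fs` samples (200 at 1000 Hz, 300 at 1500 Hz). 1500 Hz data is
not resampled; windows are defined in milliseconds and converted per trial.

## Features

* **IAV** `(1/N)·Σ|x_i|`.
* **AR(4)** via the Yule–Walker autocorrelation method (`statsmodels`,
  biased/MLE autocovariances) — deterministic and stable; a constant
  signal raises a degenerate-autocorrelation error.
* **ZC**: count of `−x_i·x_{i+1} > 0.025`. The threshold applies to the
  *product* (units V²) — implemented literally despite the dimensional
  oddity, because that is the printed form of the statistic; an
  amplitude-difference variant (`zero_crossings_amplitude`) is provided
  for comparison.
* **HIST**: 9 equal bins spanning `[−ref_m, +ref_m]`, `ref_m` the muscle's
  maximal absolute value over the *calibration* set, out-of-range samples
  clamped into the outer bins, counts normalized to relative frequencies
  (sum 1, making 1000 and 1500 Hz sessions comparable). During validation
  the calibration set is the training split of each iteration only; the
  alternative — calibrating on all conditions and repetitions at once —
  leaks the test trials' amplitude range into the features, and a
  regression test pins the leakage-free path.

## Davies–Bouldin feature quality

Dispersion is the mean *squared* distance to the class mean (no square
root), the between-class distance is Euclidean, and
`DB = (1/K)·Σ_i max_{j≠i}(S_i+S_j)/D_ij`. This literal index scales
linearly with the data scale (`S ∝ s²`, `D ∝ s`), asserted exactly in a
test; `classic=True` selects the RMS dispersion, which restores scale
invariance. Because of that scale dependence, `rank_features` z-scores each
feature dimension before scoring so families with different physical units
(volt-scale IAV, count-scale ZC, unit-scale HIST) are ranked on a common
footing; pooling is one cloud per family over all trials, labels =
directions.

## Classifier and validation

SVC with `kernel="rbf"`, `gamma = 1/(2σ²)`, σ = 2, one-vs-one multiclass.
The misclassification cost C is surfaced in the API and defaults to 1.
HIST features are used as-is (bounded in [0, 1]); AR/ZC/IAV are z-scored
with statistics fitted on the training split. Holdout splits are
stratified by direction — at 15 trials per class an unstratified 70/30
split can empty a class — and mutually exclusive by construction;
`shuffle_labels` (chance control) and `test_on_train` (optimism control)
are explicit flags. Iteration i uses seed `[seed, i]`, reported per
iteration for replay. Confusion matrices are column-normalized (columns =
actual direction, each column sums to 100%).

## Coefficient of Expressiveness

Per trial: eigendecomposition of the channel covariance of the signed
filtered window (covariance, not correlation — channels are deliberately
not variance-normalized, since relative amplitude carries the relevance
information); `n` = smallest eigenvalue prefix reaching 80% of total
variance (ties resolved by ≥, minimality checked against brute force in
tests); `c_il` = |Pearson r| between the PC-i score series and channel l —
the absolute value is a design decision, since summing signed correlations
could make the index negative and the normalization to a maximum presumes
nonnegativity; `k_l = Σ_{i≤n} c_il·λ_i / Σλ`; CoE = `k/max k`, so exactly
one muscle (or all, under exact symmetry) scores 1; CoE ≤ 0.7 is stored as
0 (non-relevant). Thresholding happens per trial, *before* cross-trial
averaging. A constant channel gets correlation 0 rather than NaN.

Profiles average thresholded CoE per (muscle, direction), pooling trials
(and subjects when given a group), with half-width `1.96·sd/√n` (NaN below
2 trials). Abnormality flags compare a patient profile to a reference:
preferred-direction shift (argmax direction differs, both profiles tuned),
loss of tuning (CoE_M range < 0.2 where the reference is tuned),
antagonist co-activation (CoE_M ≥ 0.5 in two opposite directions), trunk
involvement (a back muscle active where the reference CoE_M < 0.3). The
polar rendering connects the four directional anchors directly; smoothing
interpolation is a display concern left to the optional plotter.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic cohorts sized for
a desk machine: 9 healthy subjects × 60 trials for parameter recovery
(20 holdout iterations), 3 subjects per severity level for the degradation
sweep (5 iterations), and a single 1360-trial session for the chance-level
control (≥ 400 held-out trials per iteration, 3 iterations). Sessions are
bit-identical for a fixed (subject, design) pair; the report bundle embeds
the master seed and a configuration hash and is byte-identical across
repeated runs.

## What passing tests show — and what they do not

The generator realizes the *assumed* structure of the analysis: clean
cosine tuning, stationary band-limited noise, a single burst per trial, no
line interference, no electrode lift, no fatigue, no sub-movement
corrections. On such data healthy decoding is near-ceiling and CoE
recovers every muscle's preferred direction; recorded human EMG is noisier
in all of these respects and decodes worse. The package's synthetic results
therefore validate the *pipeline* (that the implemented statistics measure
what they claim, that degradation orderings have the right sign), not the
numeric accuracies attainable on clinical recordings. Known limitations:
no motor-unit-level physiology, no force/torque model, no artifact
rejection or MVC normalization, and the stroke model perturbs tuning
parameters rather than simulating lesioned motor control.
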