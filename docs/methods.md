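# Methods

This note documents the models, estimators, parameters and design choices
behind `dne`, and what the synthetic validation does and does not establish.

## Input model and preprocessing

A recording is a set of pose sequences keyed by skeleton tree (H2 = 2-D
hand, B2 = 2-D body, B3 = 3-D body) and side.  Right and left body parts are
stored as separate sequences with identical joint indexing; 2-D pose is
flipped to mathematical y-up on load so "vertical wrist position" increases
upward.  Keypoints with confidence below 0.1 (configurable) are treated as
missing.

Every recording is normalized by a body-derived reference length — the
forearm (`‖wrist − elbow‖`, median over frames, averaged over the two sides)
for the upper-limb tests, the pelvis–neck distance for gait — making all
coordinates unit-free and the features invariant to camera distance.  The
symmetric two-side forearm average avoids biasing the left–right asymmetry
features.

Smoothing is a running median followed by a Savitzky–Golay filter, applied
per keypoint and axis after linear interpolation of missing-data gaps up to
0.1 s (longer gaps flag the sequence unreliable).  Windows are specified in
seconds and converted to odd frame counts, so behaviour is fps-independent.
Defaults: median 0.05 s (3 frames at 60 fps), SG 0.2 s (13 frames) at
polynomial order 5.  The defaults were chosen for band fidelity: voluntary
repetitive movement in these tests lives at 1–4 Hz, and this combination
attenuates a 3 Hz sinusoid's amplitude by under 1%, whereas a wider
median (5 frames) with an order-3 SG window distorts the band by several
percent — enough to corrupt amplitude features.

## Cycle detection and per-cycle features

Local extrema are detected with a prominence threshold (default 0.2 of the
signal's global range) and a minimum spacing (0.15 s upper-limb, 0.3 s
gait), then forced to alternate min/max (of two same-type neighbours, the
more extreme survives).  A cycle spans consecutive minima; its period is
their spacing, its amplitude the rise from the opening minimum to the
included maximum.  Extremum *values* are refined by a local parabolic fit
over ±2 frames, which averages sample noise instead of taking a single
draw.  With fewer than two detected cycles every cycle-based feature is
undefined (NaN), which propagates to feature tables as missing cells —
never zero — and is median-imputed (training folds only) before modeling.

The extrema-based frequency is cross-checked in the tests against an
independent FFT periodogram oracle (zero-padded 8x for grid resolution);
the two agree within 2% on clean periodic signals across 1–4 Hz.

**Finger-tap amplitude.**  The tapping signal is the thumb–index distance.
A Euclidean distance folds measurement noise upward near finger contact (it
cannot go negative), biasing per-cycle minima by roughly the residual noise
scale and hence shrinking small amplitudes by a few percent.  Amplitude is
therefore measured on the *signed aperture*: the relative fingertip vector
projected onto each cycle's opening direction, which is unbiased at contact.
Cycle timing, speed and acceleration still use the distance series.

**Velocity angle (FTF).**  `θ(t) = atan2(ẏ, ẋ)`, with the two-argument
arctangent (a single-argument quotient is undefined at ẋ = 0), unwrapped
per cycle, resampled to 100 points, and compared across all cycle pairs by
Pearson correlation.  Velocity components are smoothed with a 0.1 s boxcar
first: at the slow turning points the speed is small and the winding
direction must be decided by signal, not noise.

**Path smoothness.**  Each reaching half-cycle's 2-D points are fit by
separate quadratics in a per-point parameter, initialized from normalized
chord length and refined by three rounds of foot-point projection
(parameter correction).  PS is the ratio of the actual polyline length to
the fitted curve's length at the same parameters.  The alternating
fit/project scheme converges linearly; exact quadratic arcs sampled at
non-constant speed come back as PS = 1 within ~1e-4, well inside any
tolerance used here (smooth motion ≈ 1, tremor ≫ 1.05).

**Stability (FT/FR).**  The wrist/elbow stability index is the mean over
frames of the right–left joint separation divided by the right joint's
distance *from the pelvis*.  Anchoring the denominator at the pelvis makes
the index translation-invariant; a raw image-origin distance would change
with camera framing.

## Gait analysis

The 3-D pose is pelvis-relative, so the subject's global position comes
from the 2-D pelvis track, synchronized by frame index.  Segmentation
thresholds the pelvis speed (velocity smoothed with a 0.25 s boxcar):
stand-up runs from the first crossing of 0.3 units/s until speed stays
below it for 0.25 s with the pelvis within 5% of its standing height
(median height over the upper half of the height range); turns are slow
spans (≥0.2 s, horizontal speed < 0.3) across which the horizontal velocity
reverses sign; walks are the sustained-motion spans (≥0.5 s) in between.

Step time/length/width are the extrema of the feet-distance signal inside
walking segments (extrema within 0.25 s of a turn boundary are discarded);
cadence and walking speed are per-walk-segment counts and pelvis path
lengths.  The knee angle is the angle at the knee between the vectors to
hip and foot (π = straight leg).  Right/left symmetry is computed per
stride (two consecutive steps): both sides' series are resampled to 100
points and the correlation is maximized over integer lags up to half a
stride, absorbing the physiologic half-stride phase offset so only shape
dissimilarity lowers the score.

## The synthetic simulator

Generators emit raw-coordinate recordings plus their ground truth; all
randomness flows from one seed (identical specs are bit-identical).
Defaults mirror the test protocol: 15 s at 60 fps for the upper-limb tests,
45 s for SAW; tapping at 2 Hz with unit (forearm-length) amplitude; rolling
at 1.5 Hz with 0.3-unit radius; gait with 0.55-unit steps every 0.55 s, six
steps per pass, three passes, 1.5 s time-to-stand; isotropic keypoint noise
of 0.01 units.  Impairment presets quantify the physical manipulations as
parameter changes: the rubber band scales one hand's (amplitude, frequency)
by (0.4, 0.6); the wrist brace slows both rolls to 0.6x and halves the
braced radius; FTF impairment adds a 6 Hz perpendicular tremor (5% of the
arc scale); the knee brace is described below.  Cohorts add lognormal
subject random effects (10%) for inherent speed/size variation and smaller
per-recording device jitter (2%), then produce normal and impaired
recordings on two devices per subject.

Two generator choices deserve note, both made for physical realism rather
than convenience:

* **FTF reaching is a narrow loop, not a perfect retrace** (default lateral
  width 0.06 units, settable to 0).  On an exact out-and-back arc the
  fingertip velocity vanishes at both turning points and the velocity-angle
  winding direction becomes noise-determined — a degenerate estimand.  Real
  repetitive reaching traces a loop; with one, the velocity angle winds
  continuously through each cycle and its cross-cycle consistency is
  well-defined.
* **The knee brace changes the flexion profile's shape, not just its
  scale.**  Correlation is scale-invariant, so merely scaling one knee's
  range cannot lower the aligned right/left knee correlation.  The braced
  leg therefore follows stiff-knee gait: flexion saturates at
  (1 − restriction) of the normal peak, the swing-phase flexion bump is
  delayed (15% of a stride at full restriction) and broadened (up to 1.7x),
  and band-limited compensatory wobble (~0.3 s correlation time, ~7° rms at
  half restriction) is added; step length shrinks by factor
  (1 − 0.6 · restriction).  At half restriction this produces a mean
  knee-symmetry drop of ≈0.13 and a 30% step-length reduction — magnitudes
  in the clinically reported range for stiff-knee gait, and detectable but
  not trivial (effect ≈ 3–10x the noise floor).

The SAW timeline includes a 0.5 s standing pause after rising (subjects
stand before walking; without it the speed-thresholded stand-up boundary
merges into the first pass) and 0.2 s gait-initiation/termination pads at
pass edges, keeping genuine first/last steps clear of the turn-boundary
exclusion margin.

What passing these tests shows: the estimators recover known kinematics
under plausible noise, the symmetry features respond to the modeled
impairments in the right direction and magnitude, and the
feature-plus-classifier stack separates the presets on unseen subjects.
What it does not show: robustness to real pose-estimator failure modes
(identity swaps, occlusion-correlated errors, depth ambiguity), to
non-frontal views, or to the heterogeneity of real patients; classification
numbers on synthetic cohorts are upper bounds set by the presets'
separability, not clinical performance estimates.

## Classification

Models: RF (500 trees), GBM/XGBoost (200 trees, depth 3, lr 0.1), L2
logistic regression (C = 1), RBF-SVM (C = 1, gamma = scale), one-hidden-
layer MLP (64 ReLU units, early stopping).  Each fold fits an
imputer → scaler → model pipeline on its training rows only; metrics
(accuracy, precision, recall, specificity, F1, AUC, average precision; the
impaired class is positive) are averaged over folds.  Subject-based splits
shuffle subjects with the seed and partition them into folds, so with 20
subjects each fold tests on 4 held-out subjects.  PCA projections z-score
features first and fix component signs by making each component's
largest-magnitude loading positive.  The subject-wise distance analysis
normalizes the A-A / N-N / N-A distances per feature by the maximum N-A
across subjects; it is reported over a subset of features that the
impairment manipulations actually move (asymmetries and impaired-side
means) — features unaffected by a manipulation carry no class signal and
are not informative about device robustness vs class separation.

## Problem sizes used in validation

The shipped tests and the acceptance script use recordings at protocol
length (15 s / 45 s, 60 fps), a 3×3 grid of commanded frequency
{1, 2, 3} Hz × amplitude {0.5, 1, 1.5} for parameter recovery, 50 seeded
signals for the FFT cross-check, 20 paired replicates for the knee-brace
sensitivity, and 20-subject × 4-recording cohorts per test for
classification — sizes at which every estimate is stable while the whole
suite runs in minutes on one CPU.
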