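# Methods

`wearact` classifies basic activities of daily living — sitting/standing,
laying, walking, stairs, and transition states — from a chest-worn IMU
sampled at 25 Hz, under the two data inconsistencies that plague long-term
monitoring of older adults with mixed device generations: per-device
baseline shifts and sensor mis-orientation.  This note documents the model,
the tunable parameters, the synthetic cohort the tests run on, and the
design decisions taken where the procedure was genuinely open.

## Signal model and preprocessing

Raw tri-axial acceleration `a(t)` (g units) is decomposed into a gravity
component `g(t)` (3rd-order Butterworth low-pass at 0.3 Hz, applied
forward–backward so the decomposition is zero-phase) and a body component
`b(t) = a(t) − g(t)`.  The decomposition is exact by construction.  The
body jerk is the first difference scaled by the sampling rate, and each
tri-axial signal also yields its per-sample Euclidean magnitude.  The
cutoff and filter order are configurable; 0.3 Hz cleanly separates postural
(quasi-DC) content from gait (≥ 0.9 Hz) at this sampling rate.

A width-3 median filter is available for telemetry spike removal but is
*not* part of the default chain: a per-axis order statistic does not
commute with rotation, and the rotation-invariant feature path depends on
that commutativity holding exactly.

## Windowing and labels

Windows are 68 samples (2.72 s) with 50% overlap (hop 34 samples, 1.36 s).
Six raw annotations map onto five classes: sitting and standing merge
(SIT_STAND), upstairs and downstairs merge (STAIRS), and the first 5 s of
every annotated interval is re-labelled TRANSITION.  A window takes the
majority label of its samples; ties go to the chronologically earlier
interval (deterministic and favouring the established activity).  Trailing
partial windows are dropped; annotation gaps simply yield unlabelled
windows, which training skips.

## Feature spaces

Two fixed manifests are shipped as plain-text YAML and rebuilt (and
verified) from code at import time.

**Axis-dependent, 254 features.**  Sixteen primitives (mean, SD, median
absolute deviation, max, min, signal magnitude area, energy, IQR, spectral
entropy, 4 Yule–Walker AR coefficients, pairwise axis correlation, dominant
spectral bin, spectrum-weighted mean frequency, spectral skewness and
kurtosis, and band energies) applied per signal:

| signal        | layout                                            | count |
|---------------|---------------------------------------------------|------:|
| body_acc      | 8 stats ×3 axes, AR(4) ×3, SMA, 3 correlations    |   40  |
| gravity_acc   | as above without correlations                     |   37  |
| body_jerk     | as body_acc                                       |   40  |
| magnitudes ×3 | MEAN, STD, ENERGY                                 |    9  |
| f_body_acc    | 12 stats ×3, SMA, 3 corr., 8 band energies ×3     |   64  |
| f_body_jerk   | as f_body_acc                                     |   64  |

Spectra are 64-bin one-sided magnitude spectra of the mean-removed window
(length-128 zero-padded FFT, rectangular window; bin width fs/128 ≈ 0.195
Hz).  The band table — bin edges (0, 4, 8, 12, 16, 24, 32, 48, 64) — is
finer at low frequency so the postural (< 0.8 Hz), stair (≈ 0.9–1.4 Hz)
and walking (≈ 1.4–2 Hz) fundamentals and their first harmonics land in
distinct bands.  Signal entropy is pinned as the Shannon entropy of the
normalized magnitude spectrum for time- and frequency-domain blocks alike.

**Rotation-invariant, 90 features.**  Every per-axis triplet (fX, fY, fZ)
collapses to the magnitude of the corresponding 3-D vector; features
computed on magnitude signals pass through; per-axis-pair correlations are
dropped (they are neither triplets nor orientation-insensitive).  Two
refinements keep the reduction honest about invariance:

* primitives *quadratic* in the signal (ENERGY, BANDS_ENERGY) collapse via
  `sqrt(fX + fY + fZ)` — the magnitude of the underlying amplitude vector —
  because the Euclidean norm of an energy triplet is not rotation
  invariant while the square root of its sum is exactly so;
* the tri-axial time-signal SMA (an L1 statistic, strongly orientation
  sensitive) is replaced by the mean L2 magnitude, i.e. the corresponding
  magnitude-signal MEAN.  The frequency-domain SMA remains an L1
  pass-through; its measured drift under rotation is small.

With these rules the reduced MEAN and STD norms (trace of the covariance),
all energy-scale features and all magnitude-signal features are exactly
rotation invariant (machine precision); the remaining reduced features
(order statistics, AR norms, spectral shape) are approximately stable and
carry the residual resolution the surrogate classifier uses.

Features are z-scored with the training set's per-column mean and SD
(population variant); zero-variance columns divide by 1.  The stored
parameters are applied unchanged to test data.

## Baseline harmonization

The two garment generations report accelerations on shifted scales.  Each
axis's baseline is estimated from "quiet" segments: non-overlapping 2-s
segments whose SD lies below the 0.4 quantile of segment SDs, averaged.
The 0.4 quantile captures essentially *all* static segments of the
protocol, making the posture composition of the baseline — and therefore
the baseline itself — reproducible across recordings; a very low quantile
would select a noise-driven subsample whose standing/sitting/laying mix
(and hence the estimate) fluctuates by up to ±0.3 g on single axes.
Recordings that cannot fit one segment fall back to the whole-series mean
with a warning.

Correction is a pure per-axis shift onto the reference baseline (the mean
of the training recordings' baselines), which preserves every central
moment of order ≥ 2 and is idempotent.  An optional per-axis rescaling by
the ratio of quiet-segment spreads is available behind a flag (off by
default — the documented procedure is shift-only, though a scaling
difference between devices is plausible).

## Orientation checking and model routing

The training recordings (worn correctly, −X vertical) define a reference
space; each incoming recording is routed to the axis-dependent model or
the rotation-invariant surrogate by two rules applied in order:

1. **Vertical-axis check.**  The recording's central-80% interval
   [p10, p90] on `acc_x` must lie inside the pooled training interval
   (min of training p10s, max of p90s) expanded by a 10%-of-width margin.
   The margin prevents boundary flapping; interval containment is the
   adopted reading of "the bulk of measurements in the same range".
2. **Distribution check.**  For recordings that fail rule 1 (e.g. a pure
   baseline shift), the recording is aligned to the reference baseline and
   its 16³ histogram of raw tri-axial values (up to the first hour of
   signal; bin edges span the pooled training range with 1% tail clipping,
   out-of-range values clamped so no mass is lost) is compared with each
   training recording's histogram via a 3-D Kolmogorov–Smirnov distance:
   the maximum absolute difference of cumulative sums over all bins and
   all 8 octant cumulation directions (a binned Fasano–Franceschini
   statistic; symmetric, in [0, 1]).  If the minimum distance over
   training histograms is below θ — the maximum pairwise distance among
   the training histograms — the orientation is accepted.

Rule 1 sees the recording *as measured* (a shifted baseline must be able
to fail it); reference histograms are computed after aligning each
training recording to the common reference baseline, the same space in
which every test comparison happens.  Every training recording routes
axis-dependent under its own reference space, and routing is invariant to
the order of the reference histograms.

The axis-dependent path aligns the recording to the reference baseline
before feature extraction (training features are extracted from aligned
recordings for the same reason).  The rotation-invariant path uses the
recording as measured: a per-axis shift has no meaning in an unknown
orientation, and aligning a rotated recording would inject a large
non-rotational offset into the gravity-magnitude features.

## Classification

Relief-F (multiclass; k = 10 nearest hits/misses, Manhattan distance on
min–max-scaled features, miss contributions weighted by class priors,
every instance iterated) ranks the features of each space; the
axis-dependent model keeps the top 10 of 254 and the surrogate the top 40
of 90 (defaults; both re-selectable).  An RBF-kernel SVM is trained per
space with class weights inverse-proportional to class counts (normalized
to mean 1) and a grid search over C ∈ {0.01, 0.1, 1, 10} and γ ∈ {0.1,
0.5, 1, 2.24, 3.12, 5} under stratified 4-fold cross-validation; ties
resolve to the smallest C then smallest γ.  Fold assignment is seeded, so
training is deterministic given the seed.

## Temporal smoothing

Assuming no activity lasts under 4 s, predictions are smoothed with a
centered moving majority vote over the 1.36-s prediction lattice.  The
filter support is the nearest odd integer to (minimum duration)/(hop) —
3 for the defaults; edges use truncated windows and ties keep the
incumbent label, avoiding oscillation.  The filter is idempotent on
impulse-free sequences and never invents labels.

## Convolutional models

Three layouts consume the same 68 × 9 windows (accelerometer, gyroscope,
magnetometer × x, y, z):

* **CNN1** — 5×1 kernels along time, channels in depth (input 68×1×9);
* **CNN2** — 5×3 kernels over time × sensor, axes in depth (68×3×3);
* **CNN3** — a 2-D "signal image" of rows acc/gyr/mag/acc (height 12,
  depth 1), 5×6 kernels, first-layer stride 1×3 so axis bundles stay
  aligned while every sensor pairing is seen.

Each of three conv blocks is convolution → batch normalization → ReLU
(valid convolutions, no pooling), then a ReLU dense layer with dropout and
a 5-way softmax.  When a deeper layer's kernel height exceeds the
remaining height it clamps to that height (width stays 5) and the stride
reverts to 1×1 — the minimal reading of "the same kernels in subsequent
layers" that keeps all three layouts buildable.  Batch normalization is
the adopted realization of the unspecified "normalization layer".

Per-layout defaults: CNN1 filters 65/100/45, dense 583, dropout 0.6, lr
0.0330, L2 0.0030, batch 100; CNN2 filters 100/57/10, dense 1000, dropout
0.39, lr 0.0480, L2 0.0001, batch 100; CNN3 filters 59/94/58, dense 773,
dropout 0.6, lr 0.1, L2 0.0001, batch 59; 100 epochs and plain SGD
throughout (tests and the acceptance program train 20 epochs, which
suffices on the synthetic cohort).  The layer stack is implemented
directly on numpy arrays (float32, im2col/BLAS matmuls) with seeded
initialization, shuffling and dropout, so a fixed seed reproduces training
exactly on one thread; a cohort-scale 20-epoch CNN1 run takes well under a
minute on one CPU core.

## The synthetic cohort

The generator emulates the supervised protocol — standing 1 min, sitting
1 min, walking 1 min, stairs up/down 30 s each, laying 30 s, 270 s total —
at 25 Hz with nine channels, and the two inconsistency phenomena.  It is a
statistical emulation, not a biomechanical one: the pipeline consumes
window statistics, and those are what the generator controls.

* **Postures.**  Device orientation per activity: upright (−X vertical)
  with ±5° pitch for standing/walking/stairs, a 10–20° recline for
  sitting, supine for laying (gravity on +Z; the protocol lays
  participants on a bed with the device on the sternum), all with ±3°
  per-activity jitter.  Static micro-motion is posture dependent —
  standing 0.025 g, sitting 0.012 g, laying 0.004 g of band-limited sway —
  reflecting that quiet standing sways constantly while lying is nearly
  motionless; this is what makes laying separable in the
  rotation-invariant space, where gravity direction is invisible.
* **Gait.**  Locomotion adds a step-frequency sinusoid plus harmonic on
  the vertical axis (walking 1.4–2.0 Hz, amplitude 0.10–0.30 g; stairs at
  0.60–0.82 × the subject's walking cadence clipped to 0.9–1.4 Hz,
  amplitude 0.15–0.40 g, stronger harmonic), an anteroposterior component
  at 0.4 × the vertical amplitude, and mediolateral sway at *half* the
  step frequency (left/right alternation once per stride).  Slow
  frequency (±6%) and amplitude (±20%) modulation emulates
  stride-to-stride variability; without it a perfectly stationary
  oscillation yields dozens of redundant locomotion discriminators that
  crowd every posture feature out of a top-10 selection.
* **Transitions.**  Every activity change interpolates the orientation
  (spherical interpolation) across the first 5 s of the new activity and
  adds a single slow (≈ 0.4 Hz) movement lurch with accompanying trunk
  angular rate — a posture change is one movement, spectrally below the
  gait band.
* **Sensors.**  The gyroscope oscillates during locomotion (30–60 °/s)
  and is near-silent otherwise; the magnetometer is a fixed field vector
  carried through the body orientation.  Accelerometer noise is 0.03 g.
* **Inconsistencies.**  Device-profile emulation applies per-axis offsets
  (±0.1–0.3 g) and optional scale factors.  Misplacement rotations map the
  vertical axis onto ±Y or ±Z (worn sideways, or facing up/down) with an
  arbitrary spin about the vertical and ±10° jitter: a permanently worn
  garment cannot sit at an arbitrary shallow angle, a rotation purely
  about the vertical axis leaves gravity untouched (no routing ground
  truth), and an upside-down donning is blocked by the garment's cut.
  `apply_rotation` itself accepts any proper rotation.

**What passing tests show, and what they do not.**  The generator
reproduces the statistical structure the pipeline assumes — static
plateaus, oscillatory locomotion, posture-dependent gravity, transition
dynamics, device inconsistencies — so green tests demonstrate that the
machinery (feature geometry, invariance, routing, harmonization,
selection, smoothing, training) behaves as designed under those
assumptions.  They do not demonstrate field accuracy on real recordings
of older adults: real gait is non-sinusoidal and asymmetric, annotations
carry rater noise, postures drift continuously, and real device errors are
not limited to affine distortions and fixed rotations.  Accuracies
reported by the test program characterize the synthetic conditions only.

## Default experiment sizes

Tests and the acceptance program train on 8 synthetic subjects and
evaluate on held-out subjects (4 upright for label recovery, 10 rotated
for the surrogate comparison, 40 recordings half rotated for routing);
CNN checks train CNN1 for 20 epochs on the 8-subject cohort.  These sizes
mirror the 8-train/12-test design of the motivating study and keep a full
run around a minute on one CPU core.

## Known limitations

* Laying vs sitting/standing in the rotation-invariant space rests
  entirely on micro-motion amplitude; a subject who lies restlessly will
  defeat it.
* θ calibrated as the *maximum* within-training pairwise distance is
  generous when training subjects are heterogeneous; with few training
  subjects a single outlier recording inflates it.
* The baseline concept conflates device offset with posture composition;
  it is reliable here because the protocol fixes the posture mix.
* Rotations that leave the feature set's symmetries intact (e.g. a pure
  flip of one axis combined with spectral-magnitude features) are
  intrinsically hard to penalize with sign-blind features.
* The CNN stack is single-threaded numpy: correct and adequate at
  protocol scale, not a platform for large datasets.
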