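# Methods

`motionprims` classifies upper-extremity functional primitives — *reach*
(move to contact a target object), *transport* (convey it), *reposition*
(move near it), and *idle* (stand at the ready) — from body-worn inertial
sensor data, and provides the apparatus to compare classifiers, evaluation
protocols, and sensor configurations.  Because the motivating clinical
recordings are not publicly distributable, the package ships a synthetic
generator that emulates the recording conditions; everything downstream
(featurization, classifiers, metrics, search) is data-agnostic and works
unchanged on real recordings in the documented CSV format.

## The synthetic recording model

A virtual subject wears 11 IMUs (head, sternum, pelvis, bilateral hand /
forearm / upper arm / scapula), each streaming 3D linear acceleration, 3D
angular velocity, and a unit quaternion at 240 Hz (60 Hz in the desk-scale
mode used throughout the tests; windows are specified in seconds, so
features are rate-robust).  The subject moves an object between a center
target and `n_targets` radial targets (default 8, at 20 cm), `n_trials`
times (default 5) per object (default 2 objects); each move emits the
primitive sequence idle → reach → transport → reposition.  Primitive
durations are lognormal (mean 1.0 s, CV 0.25, scaled by the subject's
movement speed) so a primitive spans roughly eight 0.25 s / 0.1 s analysis
windows.

Class-specific kinematics:

* **Movement burst.** Moving primitives carry an acceleration burst whose
  envelope is the bell-shaped minimum-jerk speed profile plus a sustained
  postural (gravity-projection) plateau while the arm is off the support.
  The single-signed envelope — rather than the biphasic acceleration trace —
  is used so the class-coding *sign* is present in every analysis window.
  Peak amplitude is `16 · distance / duration²` (a minimum-jerk move
  covering the target distance within the central part of the segment).
  The burst direction is a dominant vertical (lift/lower) component plus a
  planar component toward the radial target; the constant vertical part
  makes the sign linearly recoverable across targets.  The sign separates
  reach/reposition (+) from transport (−).
* **Grasp rotation.** Reach additionally carries a forearm angular-velocity
  burst (pronation/supination to grasp, peak 2 rad/s) that reposition lacks,
  so reach vs. reposition is separable only through gyroscope/quaternion
  channels — never through acceleration alone.  All moving primitives also
  carry a smaller arm-rotation component (1.5 rad/s) on the active-chain
  gyroscopes.
* **Site weights and signatures.** The class signal is carried by exactly
  seven sites — the active-side hand (1.0), forearm (0.9), upper arm (0.8),
  scapula (0.7), sternum (0.7), pelvis (0.7), and head (0.6); the
  inactive-side limb sites carry none.  Each site realizes the movement
  along its own characteristic direction (a fixed per-site rotation of the
  signature frame, kept ≥ 30° apart across sites), so no two sites are
  kinematically redundant.
* **Postural sway.** A latent smoothed-Gaussian sway (sd 0.8 per axis,
  0.2 s correlation time) is shared by the trunk/head/active-arm group; the
  resting arm hangs loose and drifts with its own independent latent of the
  same size.  Every site additionally carries a small independent "fidget"
  component (sd 0.2).  The shared latent induces the strong cross-channel
  correlation under which a feature-independence assumption (naive Bayes)
  degrades, while the group split means an uninstrumented-side sensor
  carries no information — not even as a sway reference — about the active
  side.
* **Subject idiosyncrasy.** Each subject has a deterministic, hash-derived
  idiosyncrasy scaled by `offset_scale` (default 0.3): a 3D posture rotation
  applied to movement directions and rotation axes, and lognormal
  multipliers on movement amplitude, grasp amplitude, and sway amplitude.
  Within-subject structure stays clean; cross-subject transfer loses margin,
  which is what makes leave-one-subject-out evaluation harder than
  stratified splitting.  Setting `offset_scale=0` makes subjects
  exchangeable.
* **Sensor-redundancy dials** (all off by default).  `site_gain_sigma`
  gives each site an independent lognormal amplitude gain per segment;
  `site_engagement_prob` < 1 makes each signal-carrying site express a given
  segment's movement only with that probability (compensatory movement
  variability: different repetitions recruit different body segments);
  `site_style_amp` adds a fixed per-site rotation "style" — each segment
  rotates about its own characteristic axis with a class-specific,
  contrast-normalized amplitude — giving each site class evidence through
  its own gyroscope channels that no other site duplicates.  Together the
  last two create the regime in which adding sensors genuinely improves
  classification, which is what sensor-configuration searches are designed
  to expose.
* **Quaternions** integrate each site's *volitional* angular velocity from
  the identity orientation (exact per-sample exponential map, renormalized).
  The slow sway is deliberately not integrated: commercial sensor-fusion
  IMUs emit drift-corrected orientation, and integrating sway would turn the
  quaternion channels into a random walk that encodes elapsed time — which,
  combined with the deterministic primitive cycle, would leak label
  information unrelated to motion content.
* **Sensor noise.** Independent Gaussian noise (`noise_sd`, default 0.2) on
  every channel, added after quaternion integration.
* `class_separation` scales every class-specific term; at 0 the four
  class-conditional signal distributions coincide exactly, giving a null
  calibration in which any classifier's expected accuracy is chance.

All randomness flows from a single integer seed per recording; identical
arguments reproduce bit-identical output.  `simulate_feature_population`
generates moment-matched labeled feature populations (multinomial class
counts, per-class independent Gaussians) for scaling studies, e.g. a
300,000-primitive population matched to an observed table's proportions,
means, and variances.

### What the generator does and does not emulate

It reproduces the *structure* of the recording conditions: channel layout,
class-distinguishing kinematics with realistic confusability (reach ↔
reposition through rotation channels only; idle ↔ weak movement), correlated
sway, per-subject idiosyncrasy, and a structured task protocol.  It does not
model limb biomechanics, orientation-filter artifacts, magnetometer drift,
sensor dropout, or the heterogeneity of impaired movement.  Tests passing on
generator data therefore validate the pipeline's correctness and the
qualitative orderings it is designed to exhibit — not clinical-grade
performance on patient data.

## Featurization

Recordings are z-score normalized per channel (population sd; constant
channels pass through as zeros with a warning).  A 0.25 s window slides by
0.1 s; a window is emitted only when fully inside the recording, giving
`floor((T − w)/s) + 1` windows per contiguous span.  Windows are labeled by
the primitive owning the majority of their samples (ties toward the earlier
segment); windows crossing segment boundaries are kept, since the window
arithmetic implies a continuous slide.  Each window yields five statistics
per channel — mean, standard deviation (population), min, max, RMS — for
550 features at 11 IMU sites (10 channels × 5), 350 for 7 sites, and 105
for 7 accelerometer-only sites (3 channels × 5).  Quaternion components are
treated as ordinary real channels.

Normalization scope: raw channels are z-scored per recording (self
normalization); inside the evaluation loop, *feature columns* are
standardized with training-split statistics and applied to the test split,
so no test information leaks into training.  (Training-derived raw-channel
statistics are also supported via the `stats` argument for streaming use.)

## Classifiers

All four algorithms sit behind one `fit` / `predict` / `predict_scores`
contract with classes fixed and sorted at fit time.

* **LDA** — closed form: per-class means, empirical priors, pooled
  within-class covariance with ridge `λ·trace(Σ)/p·I` (λ = 1e-6).  Scores
  are softmax posteriors of the linear discriminants.
* **Gaussian NBC** — per-class per-feature means and population variances
  with a variance floor of `1e-9 · max variance`; log-space likelihoods.
* **KNN** — k = 5 (configurable), Euclidean, uniform vote weighting.
  Training stores references only — no statistics, no validation scan, not
  even class enumeration — so training cost is O(1) regardless of dataset
  size, realizing the algorithm's defining property; all computation is
  deferred to prediction.  Vote ties break by smaller summed neighbor
  distance, then class order.
* **SVM (RBF)** — delegated to scikit-learn's SVC (C = 1, γ = 'scale');
  one-vs-rest decision values mapped through a logistic to [0, 1] as scores;
  prediction defers to the delegate.

Scores are posterior probabilities (LDA/NBC) or vote fractions (KNN), so
rows sum to 1; the SVM's mapped decision values are monotone in the margins,
which is all ROC analysis requires.  Models serialize to versioned JSON
(explicit parameters for LDA/NBC/KNN; the SVM delegate embedded as a
portable base64 export).

KNN's weak showing on the 550-feature generator tables (Euclidean distance
concentrates in high dimensions where most features are uninformative) is
expected and documented; no acceptance property depends on its absolute
accuracy.

## Evaluation

* **Splitting** operates on primitive *segments*: all windows of a segment
  travel together, so overlapping windows can never leak across the split.
  Stratified 60/40 splitting draws, per class, `round(0.6 · n)` of the
  class's segments for training, independently for each of 10 repeats;
  leave-one-subject-out holds out each subject once.
* **Primitive-level prediction**: window predictions within a ground-truth
  segment are aggregated by majority vote (ties → earliest class in
  canonical order).  Headline metrics are primitive-level; window-level
  confusion matrices are retained.
* **PPV**: per class, `100·TP/(TP+FP)` from the one-vs-all reduction;
  overall PPV micro-pools TP and FP, which for a complete multiclass
  confusion matrix equals accuracy (asserted as an identity test).  Reported
  as mean ± sample sd (n−1) across repeats; classes never predicted are NaN.
* **Confusion matrices** are accumulated in counts and reported
  row-normalized to percent (zero-support rows NaN).
* **ROC** is one-vs-all per class on primitive-level scores (mean window
  score per segment) pooled across repeats; AUC by trapezoidal integration;
  the optimal operating point maximizes Youden's J = TPR − FPR (a
  closest-to-(0,1) alternative is available).
* **Timing harness**: at each dataset fraction (20–100% by 10% for
  table-sized data, 25–100% by 25% for simulated populations), models are
  trained de novo and wall-clock train time plus mean per-sample test time
  are recorded.  Absolute times are hardware-dependent; only relative
  structure (e.g. KNN's storage-only training) is meaningful.

## Sensor search

`enumerate_configs` lists all 2^n − 1 non-empty site subsets (size-major,
lexicographic; refuses n > 20).  `exhaustive_search` evaluates every subset
with identical split seeds, so between-configuration differences are paired
rather than split noise; `best_per_count` reports the top configuration per
sensor count (ties → lexicographically smallest site set), and failures are
recorded per configuration without aborting the search.  For LDA (the
default search classifier) a fast path computes the full-feature pooled
scatter once per split and reads each configuration's covariance off as a
submatrix — bit-compatible with the generic `select_channels → evaluate`
route (asserted by test) and roughly an order of magnitude faster.
`compare_sensor_types` evaluates each configuration once with all 10
channels per site and once with the 3 acceleration channels, on identical
splits.

### Study conditions used by the tests and the acceptance script

* *Pipeline recovery and algorithm comparison*: 6 virtual subjects, reduced
  protocol (2 trials × 3 targets × 2 objects → 288 primitives), 60 Hz,
  default separation; 60/40 × 10 stratified splits.
* *Sensor-redundancy search*: exchangeable subjects (`offset_scale=0`),
  2 s primitives (so errors are feature-limited rather than
  boundary-window-limited), `site_engagement_prob=0.3` and
  `site_style_amp=1.0` (each site is intermittently engaged and carries
  exclusive class evidence), 15 paired repeats.  Under these conditions the
  exhaustive search's best 7-sensor configuration is exactly the seven
  signal-carrying sites, and the PPV-vs-count curve declines beyond seven
  sensors, mirroring the overfitting-driven drop the method is designed to
  expose.  Selection of the exact optimum by a wrapper search is a
  statistically demanding event; at this problem size it is the typical
  outcome (most generator seeds), not a certainty — the shipped tests pin
  the generator seed for reproducibility.

## Numerical choices and degenerate inputs

* Ridge on the LDA pooled covariance is trace-scaled, so it is invariant to
  overall feature scaling; a covariance singular despite the ridge raises a
  numerical error advising a larger λ.
* Channels with sd < 1e-12 are passed through as zeros (normalization) or
  guarded with sd = 1 (feature standardization).
* Window/stride are converted to samples by rounding; at 240 Hz the
  defaults are exact (60 and 24 samples).
* Recordings shorter than one window yield an empty table with a warning;
  single-class training sets, unknown sites, non-finite features, and
  invalid fractions raise `InvalidArgumentError` eagerly (KNN defers its
  validation to prediction time by design).
* Quaternion integration uses the exact exponential map for
  piecewise-constant rates and renormalizes each step; unit norm holds to
  1e-6 before noise injection.

## Known limitations

* Generator realism is structural, not biomechanical (see above); absolute
  PPV/AUC values on synthetic data do not transfer to patient recordings.
* The exact hyperparameters of the motivating study (KNN's k and metric,
  the SVM's C and γ) are not published; the defaults here are declared
  assumptions, so numeric agreement with published per-algorithm tables is
  not expected even in distribution.
* Window-level splitting is deliberately unsupported: segment-level
  splitting is the only leakage-free interpretation.
* The search fast path covers LDA only; other classifiers take the generic
  per-configuration route and are correspondingly slower.
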