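# Methods

This note documents the models, parameter choices and numerical conventions
behind `racewalk`, and what the synthetic validation does and does not show.

## Synthetic cohort model

Real race-walking IMU recordings for this protocol are not publicly
available, so the package generates them.  Gait signals are quasi-periodic;
each of the 42 kinematic channels is modelled as a truncated Fourier series
over the stride cycle (default 6 harmonics, projected from hand-designed
base waveforms on a 240-point cycle grid).  The design choices:

- **Axes**: x antero-posterior, y medio-lateral, z vertical.  Sagittal-plane
  angular velocity (rotation about the medio-lateral axis) is `gyr_y`;
  vertical acceleration `acc_z` carries a +g baseline.
- **Shank/foot sagittal gyro**: one dominant positive mid-swing peak
  (≈ 380–430 °/s at 80% of the cycle) flanked by negative dips at pre-swing
  and at the heel strike (cycle boundary).  This is the classic shank-gyro
  morphology that makes Salarian-style heel-strike detection well-posed,
  and the generator guarantees it by construction.
- **Vertical accelerations**: dominant second harmonic (two support phases
  per stride) with amplitudes drawn once from a fixed template bank.
- **Condition effects** scale linearly with the class-separation parameter
  δ (default 1).  Loss of contact adds a free-fall-like dip toward −g on
  pelvis and shank vertical acceleration in two ~10% flight windows per
  stride (one per step).  Knee bent adds mid-stance amplitude/phase
  perturbations to shank and thigh sagittal channels (gyro and AP
  acceleration).  δ = 0 makes the three condition templates identical, so
  downstream classification must be at chance; the distance between
  condition templates is exactly proportional to δ.
- **Athletes** differ by multiplicative perturbation of the harmonic
  amplitudes (default 10%) and by stride duration (0.70 s ± 5% between
  athletes; ± 5% CV stride-to-stride within a session).  Right-side
  templates are the left-side ones delayed by half a cycle (left/right
  symmetry, which also justifies pooling left/right strides as rows).
- **Noise**: additive white Gaussian, 0.3 m/s² on accelerations and 5 °/s
  on angular velocities — roughly the high-SNR regime of a strapped-down
  MEMS unit on a firm segment.
- **Protocol**: 8 athletes × 2 repetitions × 3 contiguous condition blocks
  (regular, LC, KB) of 120 strides each at 60 Hz; the coach channel flips
  between +g and −g at each block boundary.  The per-condition stride count
  is a free choice consistent with the reported ~121 ± 23 strides per
  condition per athlete.

What the generator does **not** model: soft-tissue artifact, sensor bias
and drift, axis misalignment, curve-versus-straight differences within a
lap, fatigue, and strides that mix conditions within a lap.  Passing the
synthetic-recovery tests therefore shows that the pipeline implements its
contracts correctly (event detection, labelling, balanced segmentation,
feature computation, classifier configuration, funnel arithmetic) at
realistic signal scales — not that the classifiers would reach the same
accuracy on real athletes.  The published benchmark tables embedded in
`racewalk.reference_results` are the bridge to real data: the funnel
reproduces their published pass/fail pattern exactly.

Determinism: every random draw flows from `numpy.random.default_rng`
seeded by (cohort seed, stage, athlete index, repetition), so a fixed
configuration reproduces the cohort bit-for-bit.

## Signal conditioning

A net 4th-order Butterworth low-pass at 20 Hz is applied as a 2nd-order
design run forward and backward (`sosfiltfilt`): zero phase preserves the
timing of gait events, and the squared half-order magnitude leaves −3 dB at
the cutoff.  The coach channel passes the same filter before transition
detection; a sign change only counts if the new sign holds for 0.5 s
(30 samples), which rejects noise crossings near the flip.  Condition spans
are half-open `[start, next_start)` with 0-based indices throughout.

## Segmentation conventions

Mid-swing peaks: prominence ≥ 0.25 × (98th − 50th percentile) with minimum
peak distance 0.7 × the cycle length estimated from the FFT-based
autocorrelation of the channel (the autocorrelation estimate is robust to
secondary positive lobes that survive harmonic truncation).  Heel strike =
first negative local minimum after a mid-swing peak; when the search window
is cut off by the end of the recording and the tail is the running minimum,
the final sample is accepted, so k complete cycles yield k events.  Pelvis
strides use left-foot heel strikes as cycle boundaries.  Trimming (3 first
+ 3 last strides per condition) is applied per side; balancing keeps the
earliest strides, a deterministic choice preferred over random subsampling.
Time normalization is linear interpolation to 100 samples (preserves
endpoints exactly; band-limited channel means survive within ~2%).

## Feature conventions

The autocorrelation is the biased estimator of the mean-removed channel,
r(τ) = (1/N) Σ (x_t − x̄)(x_{t+τ} − x̄).  Mean removal keeps the DC term from
duplicating the mean feature; with the biased normalization r(0) is the
within-stride signal power, which is what the "main peak height" feature is
meant to carry.  The "second peak" is the largest local maximum at lag ≥ 1
after the first zero crossing of r — without the zero-crossing guard the
feature would lock onto the shoulder of the main lobe.  Channels with no
qualifying peak (including zero-variance channels) report (0, 0, 0) for the
three autocorrelation features.  No scaling happens at the feature stage;
standardization is a classifier concern.

## Classifier bank

All nine models sit behind sklearn `Pipeline` objects whose first step
z-scores features with training-fold statistics (distance- and margin-based
learners need comparable scales; the toggle is `ClassifierSpec.standardize`).
Mappings to sklearn:

| name  | model | notes |
|-------|-------|-------|
| DTf   | `DecisionTreeClassifier(criterion="gini", max_leaf_nodes=101)` | 100 splits ⇔ 101 leaves; no surrogate splits |
| SVMl/q/c | `SVC(kernel, degree∈{1,2,3}, C=1, gamma=1, coef0=1)` | polynomial kernel (1 + x·y)^q at kernel scale 1; OvO is SVC's native scheme |
| kNNf  | `KNeighborsClassifier(1, euclidean)` | uniform votes |
| kNNco | `KNeighborsClassifier(10, cosine)` | cosine *distance* = 1 − similarity |
| kNNcu | `KNeighborsClassifier(10, minkowski, p=3)` | cubic distance |
| kNNw  | `KNeighborsClassifier(10, euclidean, weights=1/d²)` | squared-inverse vote weighting; exact matches take all votes |
| ANN   | `MLPClassifier((10,10,10), solver="lbfgs", max_iter=1000)` | cross-entropy objective; lbfgs is the full-batch quasi-Newton option closest to scaled conjugate gradient |

Open interpretation points, resolved as follows: the cosine expression is a
similarity and is used as 1 − similarity; the per-feature weights in the
weighted-distance expression are read as neighbour *vote* weights
(∝ 1/d²), matching the "squared inverse" naming; ANN hidden widths are not
prescribed anywhere, so (10, 10, 10) is the configurable default.  kNN
label ties resolve to the smallest class index (sklearn's argmax over
sorted classes).

Cross-validation is exactly two folds — repetition 1 trains / repetition 2
tests and vice versa — averaged elementwise into one 3×3 confusion matrix
per athlete and model.  Training is per athlete; cross-athlete pooling is
out of scope.

## Metrics, funnel, goodness index

Per-class metrics are one-vs-rest on the (possibly fractional, because
averaged) confusion matrix.  Undefined precision (class never predicted) is
0 with a warning, which can only reject, never promote, a model.  Across
athletes, means and sample SDs (ddof = 1) are taken per model.

Funnel thresholds are all 0.80, compared on values **rounded to two
decimals** — the convention under which the embedded published tables
reproduce their own printed pass/fail pattern (e.g. cells printed as 0.80
pass).  Stages: mean accuracy; minimum per-condition recall; overall
precision; minimum per-condition precision.  Survivor sets are nested by
construction.

The binary collapse merges LC and KB into "irregular" (cell sums), pooling
athletes' matrices by summation; merging cannot create new errors, so
binary accuracy is never below the 3-class accuracy.  The goodness index is
computed on rates, G = √((1−TPR)² + (1−TNR)²) with "irregular" as the
positive class; its chance value is √0.5 ≈ 0.7071 (printed as 0.70 in the
benchmark's category list, whose bound G ≤ √2 follows from the formula).
Categories: optimum G ≤ 0.25; random within 0.005 of √0.5; good between
0.25 and √0.5; bad above.

Out of scope by design: the repeated-measures ANOVA/Bonferroni comparison
of survivor F1 scores (standard hypothesis tests, delegated to established
statistical routines when needed; survivor F1 tables are reported
descriptively), ROC curves over thresholds (the classifiers emit hard
labels), real-time operation, and sensor-hardware modelling.

## Problem sizes used in validation

The stochastic recovery checks run the full default cohort (8 athletes ×
2 repetitions × 120 strides/condition, δ = 1) for heel-strike recovery
(≥ 95% within ±3 samples), stride-label agreement (≥ 95%) and per-athlete
quadratic-SVM accuracy on shank accelerations (≥ 0.85).  The chance-level
(δ = 0) check runs the complete 108-model bank on a 4-athlete ×
30-strides/condition cohort — at δ = 0 the class signal is exactly zero at
any cohort size, so the smaller cohort tests the same null while keeping
the suite quick.  Unit tests use a 2-athlete × 20-stride cohort.

## Known limitations

- The funnel's two-decimal rounding convention is load-bearing for
  reproducing the published pattern; on raw means the survivor set can
  differ at the boundary.
- The second-autocorrelation-peak convention is one of several defensible
  readings of "height/position of the second peak"; it is isolated in
  `features._second_peak` for sensitivity analysis.
- The synthetic cohort is easier than real data (stationary templates,
  white noise); survivor counts on it exceed the published 7 and should not
  be read as performance claims about athletes.
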