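# Methods

This note documents the models, parameter choices and known limitations of
`rehabpredict`. It covers only what the code computes; every number quoted
here is produced by the test suite or `scripts/acceptance.py`.

## Cohort and responder labels

The bundled cohort (`rehabpredict/data/study_cohort.csv`) holds one row
per *dataset* — a (participant, tested side) pair with pre- and
post-intervention scores. Eleven persons with MS contribute 20 datasets;
two participants contribute a single side, encoded by the absence of the
row rather than by sentinels. Demographic summaries are computed per
participant (two-sided participants never double-count), score summaries
per dataset; standard deviations use the sample (n−1) convention and a
single observation reports NaN.

Responder labels compare the improvement-oriented change (post − pre for
ARAT and BBT, pre − post for NHPT) against the published smallest real
differences for neurological subjects: 5.27 ARAT points, 8.11 blocks/min,
5.32 s. The comparison is strict (`change > SRD`); at the resolution of
the bundled scores no boundary case arises. BBT and NHPT are compared on
raw units, since the SRDs are published on raw scales. On the bundled
cohort this yields 6 (ARAT), 9 (BBT) and 6 (NHPT) responders, and the
dataset of participant 02 — the *unexpected non-responder*, with the
strongest limitations at admission — is negative on all three scales.

## Digital health metrics

A trial is a uniformly sampled stream of 3-D end-effector position (mm)
and grip force (N); the protocol inserts nine pegs per repetition, five
repetitions in full administrations. Defaults (configurable via
`MetricConfig`):

| parameter | default | rationale |
|---|---|---|
| sampling rate | 100 Hz | typical for haptic end-effector recordings |
| kinematic low-pass | 10 Hz, zero-phase 4th-order Butterworth | movement band; preserves 3–5 Hz tremor |
| force low-pass | 20 Hz | grip modulation band |
| grasp threshold | 2 N | transport requires an active grip of at least 2 N |
| approach radius | 15 mm | opens the precise approach phases around pegs/holes |
| SPARC band / threshold | 20 Hz / 0.05 | standard published parameterization |
| force-rate peak prominence | 0.1 × peak-to-peak force rate | scale-free; a monotone ramp counts zero peaks |
| aggregation across movements | median | robust to single outlier movements |
| minimum valid transports | 5 | guards against degenerate administrations |

Segmentation reads grip-force threshold crossings (with a 5-sample
debounce against sensor chatter): transport runs from grasp onset to
insertion, return from insertion to the next grasp onset (trial end for
the last cycle), and the approach phases open when the end-effector enters
the approach radius around the involved peg or hole. All segments use
half-open `[start, end)` index conventions.

Metric definitions:

* **log dimensionless jerk** = ln((T⁵/L²)·∫‖x⃛‖² dt) with segment duration
  T and traveled path length L; invariant to spatial and temporal scaling
  (asserted to 1e-9), higher = less smooth. Derivatives are repeated
  central differences on the filtered series.
* **spectral arc length (SPARC)** = negative arc length of the
  peak-normalized magnitude spectrum of the speed (or rectified
  force-rate) profile over the adaptive band up to 20 Hz; more negative =
  less smooth; amplitude- and sampling-rate-invariant.
* **path length ratio** = traveled path ÷ straight start-to-end distance
  (≥ 1; π/2 for a semicircle).
* **velocity max return** = peak speed of the return movement (1.875·L/T
  for a minimum-jerk movement).
* **jerk peg approach** = RMS jerk magnitude over the peg-approach
  segment. The non-normalized variant was chosen deliberately: the metric
  name carries no "log", and precise approach movements have no natural
  length normalization.
* **force rate number of peaks** counts prominent local maxima of the
  *signed* force-rate signal (an open choice; signed peaks map to distinct
  grip re-engagements, whereas rectification would double-count).

Confound adjustment subtracts a per-metric linear model (age, sex,
dominant-hand-tested, binary stereo-vision deficit — the last modeled
binary because no scale is specified) fitted on the healthy reference
sample by ordinary least squares and centred on the reference covariate
means; covariates outside the reference support warn but extrapolate.
Normalization then orients each metric by its worse-direction (fixed in
code: higher-worse for jerk, path ratios and peak count; lower-worse for
the SPARC variants and return velocity) and scales affinely so the healthy
median sits at 0 % and the worst impaired anchor at 100 %; the scale is
unbounded and values better than the healthy median are negative.

## Synthetic data

**Trials** are concatenations of minimum-jerk point-to-point movements
through the nine peg→hole cycles, with stationary grasp/release dwells.
The grip force is piecewise linear through the 2 N threshold (so planted
grasp/release events sit exactly on samples) with slope-matched
cubic-Hermite eases up to the plateau, making the clean force rate a
smooth narrowband bump. Impairment knobs: additive 4 Hz transverse tremor
(intention-tremor band), a transverse sinusoidal path bow (curvature
gain), and a plateau-enveloped grip-force oscillation (6 Hz). Observation
noise defaults to 0.2 mm / 0.02 N, small enough that detected transport
boundaries stay within ±2 samples of the planted events at 100 Hz.
Knob-monotonicity checks run with observation noise off to isolate the
knob. Oscillation sweeps use sub-newton amplitudes (≤ 0.4 N against a 6 N
plateau): the oscillation must perturb, not replace, the movement-related
force modulation, otherwise SPARC's peak normalization is dominated by the
oscillation line itself. Known limitation: the *transport* force-rate
spectrum of the generator is shaped by the grasp and release ramps (a
two-bump comb), so the transport force-rate SPARC is not monotone in the
oscillation amplitude; the monotone targets of that knob are the
force-rate peak count and the hole-approach force-rate SPARC.

**Reference population** (default 120 healthy, 30 impaired) draws metric
vectors from a parametric model around the unimpaired generator's
calibration medians, with planted linear age and sex effects of fixed
magnitude (2 healthy spreads per decade, 1 spread per sex step; random
signs). These magnitudes make the slopes well identified at n = 120
(|slope|/SE ≈ 35), so the OLS confound fit recovers them within 10 %.
Impaired subjects are shifted worse by 1–4 spreads; the worst per metric
anchors 100 %.

**Cohorts** draw covariates mimicking the study sample (age ~
N(56.7, 14.8²), chronicity ~ N(18, 12²) truncated at 0, 7/11 female, MS
types 6:3:2 RR:PP:SP, intervention groups 5:5:1) and a per-scale logistic
responder model P(responder) = σ(β₀ + βᵀx) on standardized covariates;
β = 0 is the exact null. Scores are constructed so SRD labeling reproduces
the drawn status exactly: responders change by (1 + margin)·SRD with
margin 0.5 (unambiguous under integer ARAT rounding), non-responders by
strictly sub-SRD noise. The planted-effect preset puts a coefficient of 10
on standardized age; the closed-form Bayes accuracy of that model is
0.945, above the 0.9 floor the recovery tests assume.

## Prediction pipeline

Encodings: sex → {0, 1}; MS type and intervention group → one-hot;
numeric features raw for trees and forests, z-scored with *training-fold*
statistics for k-NN (distance-based) and linear regression. Pinned
hyperparameters: CART with Gini impurity, unlimited depth, minimum leaf 1;
k-NN with k = 3 (odd, avoids ties at ~18 training rows); random forest
with 100 trees, √p features per split, explicit seed (default 17);
linear regression as ordinary least squares on 0/1 labels with prediction
1 iff the fitted value ≥ 0.5. A single-class training fold predicts that
class. Feature sets whose columns are absent (the disability stratum and
the conventional body-function scales are not part of the bundled cohort)
are recorded as skipped rather than failing the run.

Leave-one-subject-out folds remove all datasets of one participant; the
bundled cohort yields 11 folds (nine of size two, two of size one). Fold
predictions are pooled into one confusion matrix per configuration;
balanced accuracy is the mean of sensitivity and specificity, falling back
(with a warning) to the defined rate when a class is absent. The
best-model report selects, per outcome, the highest balanced accuracy
among configurations that classified the designated unexpected
non-responder (default `02-right`) correctly, ties broken toward fewer
feature sets.

On the bundled cohort the rounded linear regression on feature sets
{1, 6} reaches 89 % balanced accuracy for ARAT with 100 % sensitivity,
79 % specificity and 67 % precision. The default CART tree on feature set
{1} reaches 74 % balanced accuracy for BBT (67 % sensitivity, 82 %
specificity); this quantity is sensitive to CART implementation details —
the result is unchanged under impurity criterion, categorical encoding,
minimum-split and minimum-leaf variants, so the package reports its own
pinned-default value rather than tuning toward any external figure.

## Calibration and recovery checks

*Null calibration.* On synthetic cohorts with β = 0 the pooled LOSO
balanced accuracy should be at chance. Leave-one-out evaluation is known
to be pessimistically biased at small n (removing a subject shifts the
training class balance *against* the held-out labels); at the study's own
size (11 participants) this bias reaches 2–5 points, which would mask the
leakage check the calibration is for. Calibration cohorts are therefore
sized 40 participants × 2 sides (25 × 2 for the random forest, whose
~0.1 s per fit dominates single-CPU runtime at 200 replicates), and the
test asserts |mean BA − 50 %| ≤ 3 standard errors over 200 replicates.
For the rounded-regression classifier a residual pessimistic bias of
roughly 1–2 points persists at every feasible size: its decision threshold
(0.5) sits exactly at the null fitted-value mean, so the O(1/n) training
shift flips predictions with probability ∝ (pn)^(−1/2) while the
Monte-Carlo band shrinks at the same rate in n — the bias-to-band ratio is
roughly invariant. This is a real property of thresholding a regression at
the null mean, not an implementation defect; the calibration test states
the chance-level claim uniformly and is expected to flag this family.

*Signal recovery.* With the planted age effect (Bayes accuracy 0.945) and
200 datasets, every family exceeds 70 % balanced accuracy out of sample
(measured ≥ 90 % for all four).

*Problem sizes.* Unit and property tests run one trial repetition
(nine cycles, ~27 s of signal at 100 Hz) rather than the protocol's five —
the metrics aggregate per movement, so repetitions multiply runtime
without changing the contracts under test; calibration uses 200 replicates
and recovery 200 datasets as stated above.

## Known limitations

* The cohort is small (20 datasets); pooled LOSO estimates on it carry
  wide uncertainty, and tree-based results are sensitive to library
  implementation details.
* The trial generator makes no biomechanical realism claims: tremor is a
  fixed-frequency sinusoid, movements are ideal minimum-jerk segments, and
  passing its tests shows the metric pipeline's correctness and
  sensitivity, not performance on clinical recordings.
* The disability stratum used for randomization and the conventional
  body-function scales exist in the schema but only synthetic values can
  populate them; grid configurations requiring them are skipped on the
  bundled cohort.
* Correlations are reported as Pearson r with two-sided p-values; at
  n = 20 the p-values for |r| ≈ 0.5–0.6 are in the 0.007–0.02 range.
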