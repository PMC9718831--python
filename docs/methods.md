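# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices and the known limitations of `wearfit`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The estimation problem

The target is VO2max in mL O2·min⁻¹·kg⁻¹, observed through a
submaximal-test estimate (so the "ground truth" is itself noisy). The
inputs are one free-living week of minute-level wearable data — raw
acceleration, movement intensity (J·min⁻¹·kg⁻¹), heart rate, heart-rate
variability — plus anthropometrics (sex, age, height, weight, BMI) and
resting heart rate. The scientific premise is that heart-rate response
to everyday activity encodes fitness: at a fixed submaximal workload,
a fitter person's heart rate rises less above rest.

## Synthetic cohort generator

### Participant model

Latent fitness is linear in anthropometrics and habitual activity:

    v = intercept(sex) − a·(age − 48) − b·(BMI − 26) + c·(activity − 1) + ε,

with defaults a = 0.12 /yr, b = 0.35 /(kg·m⁻²), c = 4.0, residual
sd 3.3, female/male intercepts 37.4/41.6 (the `fenland_like` preset)
or 30.8/35.0 with residual sd 5.9 (`bbvs_like`). Habitual activity is
Gamma-distributed with mean 1 and sd 0.5. These coefficients were
chosen once so the fenland-like preset reproduces an observed cohort
VO2max of about 39.5 ± 5 overall and 37.4 in women, and the bbvs-like
preset a less fit 32.9 ± 7; they live in `CohortConfig`, not in code.
The observed value adds N(0, 1.5²) submaximal-test error. Resting heart
rate is generated as 88 − 0.55·v + N(0, 5²), clipped to [35, 110]
beats/min, giving the physiological negative fitness–RHR correlation.

### Sensor week

One sample per minute for `days` (default 6) days: a fixed nocturnal
low-activity block 23:30–06:30 (the simplest structure that supports
sleeping-heart-rate estimation), an awake baseline near 1 MET, and
Poisson-scheduled activity bouts (rate ∝ habitual activity × a ±15%
seasonal multiplier peaking in July; duration 10 + Exp(15) min;
intensity uniform on 2.5–7.5 METs). Heart rate follows the documented
response model

    hr_t = rhr + (hrmax − rhr)·min(1, s·L_t) + N(0, σ_hr²),
    s = β / (v·(1 + b_i)),   L_t = max(0, METs_t − 1),   hrmax = 208 − 0.7·age,

with β = 5, minute noise σ_hr = 3 bpm and a persistent per-participant
response bias b_i ~ N(0, 0.033²). The bias is the dominant observation
noise for fitness: inverting the response on any active minute yields
v·(1 + b_i), so the analytic-oracle R² against observed VO2max lands
near 0.8 under the defaults — the intended realism level at which model
benchmarking is meaningful. The bias persists across study phases
(physiology, not measurement), which is what lets a frozen model detect
fitness *change* from new sensor data. HRV is an affine decreasing
function of heart rate plus noise; raw acceleration is an affine
function of intensity plus sensor noise; ENMO is derived downstream as
a fixed monotone rescaling of raw acceleration (0.85×).

Non-wear gaps arrive as a Poisson process (0.25/day) with log-normal
durations (median 100 min, σ = 0.5 log-units) so that both sub- and
super-90-minute gaps occur; gap minutes have zero movement and missing
heart rate, and the inserted mask is kept as hidden ground truth for
scoring the detector. All randomness derives from one master seed via
keyed substreams (`seed | purpose | participant | phase`), so cohorts
are extensible without reshuffling existing participants and any single
artifact is regenerable in isolation.

### Longitudinal follow-up

Elapsed time to the repeat visit is a discretized *reflected* shifted
Gamma (elapsed = L − Gamma(k, θ), solved so the continuous law has
median 7 and IQR [5, 8] years, clipped to ≥ 4): the target quantiles
are left-skewed, which a plain right-skewed shifted Gamma cannot match.
Latent fitness moves by a clipped (±10) skew-normal delta with negative
skew, location −0.5, scale 2.8, an age effect (−0.06/yr above 48) and a
mean-reversion term (−0.15 × distance from the cohort mean). The
reversion term goes beyond the minimal delta parameterization; it makes
the delta partially predictable from baseline fitness, mirroring the
regression-to-the-mean present in repeated physiological measurements,
and produces delta-regression correlations near the modest levels such
cohorts report. Weight drifts by N(+1.5, 3²) kg; resting heart rate is
re-measured from the updated fitness.

## Sensor processing

* **HR filtering**: values outside [30, 220] beats/min, and isolated
  single-minute spikes jumping > 60 beats/min against both neighbours,
  become missing. The rule is deliberately swappable — it is a
  conservative stand-in for device-specific noise filters.
* **Non-wear**: a maximal run is flagged iff strictly longer than
  90 min with movement below 1 J·min⁻¹·kg⁻¹ (sensor noise floor)
  throughout and heart rate missing or non-physiological throughout.
  Missing HR with preserved movement is *not* non-wear (poor electrode
  contact). Flagged minutes are excluded from every downstream
  statistic.
* **Eligibility**: at least 72 h of wear (three full days).
* **METs**: intensity / 71 (1 MET = 71 J·min⁻¹·kg⁻¹); classes are
  sedentary ≤ 1.5, light (1.5, 3), MVPA [3, 6], VPA > 6 METs — the
  boundaries are inclusive/exclusive exactly as written and partition
  the axis; "light" names the otherwise-unnamed (1.5, 3) band.
* **Resting HR**: sleeping HR is the lowest-mean contiguous 30-min
  window within nocturnal (23:30–06:30) wear; averaged with a supine
  clinic value when one is supplied.

## Features

68 features: 8 statistics (mean, min, max, sd, p25/p50/p75,
least-squares slope per wear-minute index) × 5 series (acc_raw, hr,
hrv, enmo, mets) = 40; month-of-year on the unit circle (sin, cos)
using the month of the first sample with a fixed period of 12 = 2;
anthropometrics (age, sex as 0 = female / 1 = male, weight, BMI,
height) = 5; RHR = 1; and an activity-volume block = 20 (per-class
total, daily-mean and daily-max minutes; MVPA bout count/mean/max with
bouts defined as ≥ 10 consecutive minutes at ≥ 3 METs; total and
daily-mean wear hours; sedentary/MVPA/VPA wear-time fractions). The
series × statistics, month pair, anthropometrics and RHR are canonical;
the activity-volume block is this package's concrete choice for the
remaining slots, and the registry is data-driven so an alternative
composition can be swapped in without code changes. MVPA minutes count
all minutes at ≥ 3 METs by default (flag-selectable to the strict 3–6
band). Percentiles use linear interpolation; sd is the population
standard deviation.

## Preprocessing

Standard scaling (training mean/sd; zero-variance features scaled
by 1) followed by full-decomposition PCA on the scaled training data,
retaining the smallest component count whose cumulative explained
variance is ≥ 99.99% (inclusive). The exact solver and an explicit sign
convention (largest-magnitude loading positive) keep the retained count
and serialized basis deterministic; fitted arrays are frozen read-only,
serialization (JSON header + CSV component matrix at 17 significant
digits, read back with round-trip float parsing) is bit-exact, and the
training-id fingerprint travels with the transforms so downstream
models can refuse mismatched inputs. Input matrices are coerced to a
canonical memory layout before reduction so fitted parameters cannot
depend on how a caller's DataFrame happens to sit in memory. The
outcome is left in natural units (mL O2·min⁻¹·kg⁻¹), not standardized,
so RMSEs are directly interpretable.

## Models

* **Equation baseline**: HRmax/HRrest ratio method with the Tanaka
  maximum, default per-kg form 15.0·(208 − 0.7·age)/rhr. The literal
  mass-multiplied variant is available behind a flag but returns
  absolute mL O2/min, inconsistent with per-kg outcomes, hence not the
  default.
* **Linear**: ordinary least squares with intercept (scikit-learn),
  rank-deficiency checked explicitly.
* **Dense regressor**: input → [Dense(128) → BatchNorm → ELU →
  Dropout(0.3)] × 2 → Dense(1); Glorot-uniform init, Adam (1e-3) on
  MSE, batch 32, random 10% validation split, early stopping after 15
  non-improving epochs with best-validation weights restored, learning
  rate × 0.1 on a 5-epoch validation plateau. "Reduced every 5 epochs"
  admits two readings; reduce-on-plateau is the default for consistency
  with plateau-based early stopping, and an unconditional step schedule
  is config-selectable. Block order dense → batch-norm → activation →
  dropout is fixed and documented. The binary classifier is the same
  family with one hidden block, a sigmoid head and binary
  cross-entropy.
* **Implementation**: the networks are written directly in NumPy
  (`wearfit._dense`): at these sizes (≤ 68 inputs, 128-unit layers,
  thousands of rows) matmul training takes seconds, and a single seeded
  generator drives init, splits, shuffling and dropout, so identical
  seeds give bit-identical models. One numerical choice matters: the
  output bias is initialized at the training-outcome mean (log-odds of
  the base rate for the classifier), because Adam moves parameters by
  roughly the learning rate per step and would otherwise spend the
  entire epoch budget hauling the head from 0 to ≈ 40. Batch-norm uses
  ε = 1e-3 and momentum 0.99; batches of one row are skipped (batch
  statistics undefined); when a caller's training set is too small for
  the default batch/validation sizes, the task runner shrinks them
  (never below 2) rather than failing.
* **Latent space**: penultimate-layer activations in inference mode
  (dropout off, running batch-norm statistics), one 128-vector per row.

## Evaluation

Metrics are implemented from their definitions (RMSE, MSE,
R² = 1 − SSres/SStot, Pearson r, MAE, SD of absolute error, MAPE with
|truth| in the denominator) and cross-checked in the tests against
scikit-learn/scipy; AUROC is the Mann–Whitney rank statistic with 0.5
tie credit, cross-checked against an exhaustive O(n²) pair count.
Confidence intervals are 95% percentile bootstrap over 500 paired
resamples (the simplest method consistent with plain
resampling-with-replacement; BCa was not required), seed-reproducible,
with undefined resamples redrawn and counted. Delta labels: thresholds
are quantiles (linear interpolation) of the *training portion only*;
delta ≤ lower threshold → class 0, ≥ upper → class 1, middle dropped;
the 50/50 design keeps everyone with ties to class 0; unequal tails
under ties are trimmed from the threshold inward ordering by value then
participant id, so class sizes differ by at most one. Subgroup tables
split continuous variables at the test-set median with the median
assigned to the ≤ group. Bland–Altman reports the mean difference
(prediction − truth) and mean ± 1.96 sd limits. Task 2's 80/20
partition re-randomizes the longitudinal set under a fixed recorded
seed rather than inheriting any prior ordering; the plan is serialized
for audit. The delta outcome is current − future, so positive deltas
mean fitness decline.

## Subtyping

Exact (non-approximate) Euclidean k-NN with distance ties broken by
participant id; k = 5 by default. The "original space" for
original-vs-latent comparisons is the scaled + PCA-projected feature
space — the model's actual input — because raw features mix units; a
raw-feature space can be supplied explicitly. Neighbour distances are
computed in the full-dimensional spaces, not the 2-D projection. t-SNE
(scikit-learn, perplexity 50, PCA init, fixed seed) is used strictly as
an off-the-shelf projection for visualization, with the population >
3 × perplexity validity rule enforced; the fitness label is only ever
used for colouring. The fraction of queries whose latent neighbourhood
total is smaller than the original-space total is reported as a logged
diagnostic, not an enforced claim.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the measured properties are stable: 5000
participants for generator fidelity, 100 for exact recovery, a
1000-participant cohort (half longitudinal) for the end-to-end pipeline
benchmark, and a 2675-participant longitudinal cohort for the
delta-classification designs, with medians over 5 seeds where a
training stochasticity enters. Brute-force exactness suites use ≥ 500
random instances per primitive.

## Known limitations

* The generator's heart-rate response is a single saturating-linear
  form with one bias parameter; real HR kinetics (on/off transients,
  thermoregulation, medication) are richer, so real-data accuracy will
  differ from synthetic benchmarks.
* Activity bouts are intensity-homogeneous and type-free; features
  relying on bout microstructure are only weakly exercised.
* The delta model ties fitness change to age and baseline fitness but
  not to changes in the activity schedule, so Task-2/3 performance on
  synthetic data reflects that specific signal structure.
* The submaximal-test error is homoscedastic Gaussian; real
  extrapolation error grows at the extremes of fitness.
* t-SNE coordinates are seed-reproducible but not comparable across
  library versions.
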