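# Methods

## The model

`sepkin` treats a monitored patient as a point moving in the space spanned by
six bedside vital signs — heart rate (HR, beats/min), pulse oximetry (O2Sat,
%), temperature (Temp, °C), systolic and diastolic blood pressure (SBP/DBP,
mm Hg) and respiration rate (Resp, breaths/min). The patient's position at
hour *t* is the vector of (normalized) vitals,
r_A(t) = [x₁(t), …, x₆(t)]. With an hourly sampling step the velocity and
acceleration are plain first differences:

    v_A(t) = r_A(t) − r_A(t−1),        a_A(t) = v_A(t) − v_A(t−1).

A single static **sepsis position** r_B is estimated as the component-wise
median of the positive patients' vitals at their sepsis onset (onset = the
last row of an onset-truncated series). Relative to this target,

    r_{A/B}(t) = r_A(t) − r_B,         d(t) = ‖r_{A/B}(t)‖₂,
    e(t) = r_{A/B}(t) / d(t),
    ProjV(t) = v_{A/B}(t) · e(t),      ProjA(t) = a_{A/B}(t) · e(t).

Because r_B is static, v_{A/B} and a_{A/B} equal the patient's own velocity
and acceleration; e(t) is the unit direction from the target to the patient.
ProjV < 0 means the patient is closing in on the sepsis position; ProjA is
the rate of change of that approach. The per-hour **kinematics features
(KF)** are the 8-vector [e₁…e₆, ProjV, ProjA]; the hypothesis the package
lets you test is whether classifiers fed KF inputs detect incipient sepsis
better than the same classifiers fed the raw vitals (VS inputs).

Boundary conventions: v(0) = 0 and a(0) = a(1) = 0 so the feature matrix
keeps the full window length; when d(t) ≤ 1e−12 (patient numerically at the
target) e(t) is the zero vector and both projections are 0. Medians over an
even number of positives take the midpoint of the two central order
statistics. Projections at hour *t* use e(t), the current direction.

## Preprocessing cascade

Raw per-patient files (pipe-separated, one row per hour, `NaN` for missing)
pass through, in order:

1. **Onset truncation** — a positive patient's series is cut at the first
   row whose `SepsisLabel` is 1, making onset the last row. (Label spans are
   collapsed by this first-flag rule; the convention is ours.)
2. **Exclusions** — drop patients with fewer than `min_rows` (default 36)
   hourly registers, then patients with any vital sign entirely missing. The
   short-series rule is applied first, so nobody is counted twice.
3. **Limit clipping** — readings outside closed per-sign operating intervals
   become missing. Defaults (HR 20–300, O2Sat 50–100, Temp 30–45,
   SBP 40–300, DBP 20–200, Resp 4–60) are wide plausibility bounds for
   catching sensor/typing errors; the table is configurable because any
   specific deployment should substitute its own source.
4. **Windowing** — keep the last 48 h; shorter series get leading all-missing
   rows, so row index = window hour for every patient.
5. **Hourly-mean imputation** — a missing cell (sign j, window hour t) takes
   the mean over all cohort patients of the present values of j at t. Means
   are computed on the window-hour index (the only time frame all patients
   share), pooling positives and negatives.
6. **Linear interpolation** — leftover gaps are interpolated against the hour
   index; leading/trailing gaps take the nearest present value (linear
   interpolation is undefined there).
7. **Smoothing** — trailing 3-point moving average; the window shrinks at
   t = 0, 1 so the series keeps 48 rows.
8. **Max-normalization** — each sign is divided by its cohort-wide maximum
   (minimum fixed at zero), mapping values into [0, 1]. By default the maxima
   are fitted once on the whole processing cohort, which intentionally mirrors
   how the feature tables are built for the classifier comparison; this leaks
   scale information across CV folds. `normalize_by_max` on a training subset
   plus `apply_maxima` on held-out data is the leakage-free alternative.
9. **Balancing** (optional) — all positives plus a seeded uniform subsample of
   negatives.

## Classifier comparison

Inputs are per-patient matrices truncated HBS hours before the window end
(HBS = hours before sepsis; HBS = 6 on a 48-row window leaves 42 rows, so an
accuracy at HBS = 6 is a six-hour-early prediction). KF inputs are 42×8,
VS inputs 42×6. Five classifiers are compared:

* **LSTM** — one layer, 128 hidden units, 20 % dropout on the final hidden
  state, sigmoid output; binary cross-entropy, Adagrad, batch size 64.
* **CNN** — one 1-D convolution over time (64 filters, kernel 3), ReLU,
  global max-pool, dense sigmoid head; same loss/optimizer.
* **Linear NN** — a single dense layer on the flattened input.
* **Logistic regression** and **decision tree** (scikit-learn defaults,
  flattened input) as non-sequence references.

The recurrent and convolutional nets are compact numpy implementations
(`sepkin.nn`) with exact backpropagation (verified against finite
differences in the test suite). Training choices not fixed by the
architecture: Adagrad learning rate 0.1, up to 50 epochs with early stopping
on a training-loss plateau (patience 5, min-delta 1e−4), global-norm
gradient clipping at 5, Glorot input kernels, orthogonal recurrent kernel,
forget-gate bias +1, and a zero-initialized dense head so training starts
from the base-rate prediction (with Adagrad's accumulator this prevents the
first noisy head gradients from dominating the schedule). On the synthetic
drift cohorts the training loss typically sits on a plateau near the
base-rate loss for tens of epochs before descending, so for the larger
evaluation runs we use a fixed 100-epoch schedule with early stopping
disabled; with small patience the stopper tends to fire mid-plateau.

Evaluation is stratified k-fold cross-validation (default k = 5, the
field's usual choice) with one fold partition shared by
every model and both representations, so KF−VS accuracy differences are
paired. Accuracy thresholds probabilities at 0.5. Fold standard deviations
are across folds. Calibration curves bin the pooled out-of-fold
probabilities into equal-width bins (default 5, scikit-learn's default) and
plot observed positive fraction against mean predicted probability.

Determinism: simulator, folds and the numpy nets are exactly reproducible
from their seeds on a fixed BLAS thread count; the scikit-learn models are
deterministic given `random_state`.

## Synthetic cohorts

The generator (`sepkin.simulate`) emulates the structure the method assumes,
not full physiology:

* **Negatives** fluctuate about baseline vitals with stationary AR(1) noise
  (autocorrelation 0.8 — hourly vitals are strongly autocorrelated; marginal
  σ per sign defaults to roughly a third of typical cohort spreads:
  5 beats/min, 0.8 %, 0.17 °C, 6 mm Hg, 3.5 mm Hg, 1.5 breaths/min).
  Baselines default to typical non-septic ICU means (85.65, 97.39, 37.10,
  120.87, 60.26, 18.40). O2Sat is capped at 100 %.
* **Positives** follow the same process, but over their final `drift_hours`
  (default 12) the *mean* path moves linearly from baseline to a planted
  sepsis point, so realizations end near — in general never exactly at — the
  point; the last row carries the sepsis flag. The default planted point
  (98, 95.5, 37.9, 90.91, 55, 21.65) is a deteriorating-patient picture
  whose SBP ≤ 100 and Resp ≥ 22 components match two bedside screening
  (qSOFA) criteria for sepsis.
* **Corruption**: each cell goes missing with probability 0.10; with
  probability 0.01 it is replaced by an out-of-range spike that limit
  clipping should catch. Series lengths are uniform on 30–120 rows, so a few
  patients also exercise the short-series exclusion.
* Per-patient RNG substreams are spawned from the master seed: a patient's
  data is invariant to cohort composition, and identical configurations give
  byte-identical cohorts.

What passing tests on these cohorts shows: the formulas are implemented
faithfully, the planted geometry is recovered, and the harness detects the
planted KF signal. What it does not show: performance on real ICU data,
where missingness is informative, noise is non-Gaussian and non-stationary,
onset labeling is noisy, and the drift toward deterioration is neither
linear nor shared across patients.

## Problem sizes and numerical choices

The shipped evaluation scale (used by the test suite and the acceptance
script) is a few hundred synthetic patients with 5-fold CV — large enough
for the planted signal to dominate fold noise, small enough to run on one
CPU in minutes. Key tolerances: zero-distance threshold 1e−12 (configurable
in `sepkin.kinematics`); unit-norm assertions at 1e−9; oracle-equivalence
tests at 1e−12 (the implementation and the test oracles perform the same
arithmetic in the same order, so agreement is essentially exact).

Degenerate inputs: an empty positive set makes the sepsis position
undefined (error); a sign with no observed value anywhere fails
interpolation loudly (the exclusion step makes this unreachable in the
normal pipeline); a sign with non-positive cohort maximum fails
normalization (impossible for real vitals).

## Known limitations

* The sepsis position is a single static median; moving or per-subgroup
  targets are out of scope (the estimator tag in `SepsisPosition` leaves the
  seam for them).
* Cohort-wide normalization leaks scale across CV folds by design fidelity;
  use the fit-on-train functions if that matters for your question.
* Accuracy at a fixed 0.5 threshold is the only headline metric; no
  utility-weighted or ROC-optimizing evaluation.
* The numpy networks are single-threaded and sized for desk-scale cohorts,
  not for tens of thousands of patients.
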