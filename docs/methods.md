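# Methods

## Problem setting

The package estimates the short-horizon risk of iatrogenic withdrawal
syndrome (IWS) for a pediatric ICU patient after extubation. Time is
anchored at extubation (t = 0) and divided into consecutive 4-hour epochs.
An *observation window* is six consecutive epochs (24 h of history); the
*prediction epoch* is the single epoch that follows. The binary outcome is
whether any WAT-1 assessment of at least 3 is recorded during the
prediction epoch. Windows slide forward one epoch at a time, so a patient
with K epochs contributes max(0, K − 6) labelled windows; patients with
fewer than seven epochs of data contribute none, because a full 24-hour
history is required before a prediction is made.

## Featureization

Each epoch is summarised into a fixed-order vector of 66 features
(`iwsrisk.schema`, version 1.0):

| block | features | count |
|---|---|---|
| vitals (temperature, heart rate, SBP, DBP, respiratory rate, MAP) | min, max, max-delta, mean, measurement count | 30 |
| medications (fentanyl, morphine, hydromorphone, methadone, midazolam, dexmedetomidine, lorazepam, propofol) | epoch dose rate (mg·kg⁻¹·h⁻¹), cumulative dose (mg·kg⁻¹), previous-epoch dose (mg·kg⁻¹), cumulative exposure (h) | 32 |
| scalars | age (months), prior withdrawal-epoch count, epoch index, ventilation duration (h) | 4 |

Design choices inside this schema:

* The epoch dose feature is a *rate* (total epoch dose ÷ weight ÷ epoch
  length) so that sweeps over epoch length remain comparable.
* Cumulative exposure duration counts whole epochs containing at least one
  administration, multiplied by the epoch length; administration start/stop
  times are not modelled in the input schema.
* The prior-withdrawal count at epoch e is the number of epochs before e
  whose WAT-1 record crossed the threshold, plus any documented pre-ICU
  history; the epoch-index feature is the 1-based count of epochs since
  extubation.
* Epoch intervals are half-open [start, start + 4 h); a record exactly on a
  boundary belongs to the later epoch.
* Prediction epochs without any WAT-1 assessment are labelled negative by
  default; an `exclude` mode drops such windows instead. Neither choice is
  obviously right — absence of an assessment usually means no clinical
  concern, but it is not a measurement — so both are exposed.

Missing vital epochs are imputed in three stages: the previous epoch's mean
carried forward (a deliberate one-epoch horizon, i.e. "within the previous
four hours", not unbounded last-observation-carried-forward); otherwise the
patient's mean over all their measurements of that variable; otherwise the
training-cohort mean. An imputed epoch is treated as one repeated
measurement (min = max = mean, max-delta = 0) and keeps measurement count
0, so sparse observation remains visible to the model. After imputation the
pipeline asserts zero missing values.

Scaling is min-max to [0, 1], fitted on training-split windows only and
clipped on application; a feature constant in training maps to 0. Splits
are by patient (default 20% test, then 20% of the remainder as validation
for early stopping and calibration), so no patient contributes windows to
two splits.

## Model

A unidirectional, manually unrolled LSTM with L layers (default 2) and
hidden size H (default 64) consumes the six scaled epoch vectors. The cell
follows the standard equations (input, forget, output gates; tanh
candidate; Hadamard-product state updates). The top layer's final hidden
state passes through batch normalisation, dropout (training only) and a
fully connected layer to one logit; a sigmoid yields the risk probability.

* **Initialisation.** Every LSTM and head weight and bias is drawn i.i.d.
  uniform on [−1/√H, +1/√H]. Batch-norm scale/shift start at the identity.
* **Batch-norm placement.** Applied to the final hidden state before
  dropout and the head ("after the LSTM layers"); at inference it uses
  running statistics and is a fixed affine map, which the explainer folds
  into the head.
* **Training.** Analytic backpropagation through time (verified against
  central finite differences to 1e-4 relative error), Adam at lr 1e-3,
  batch size 64, binary cross-entropy with logits clamped to [−30, 30]
  inside the loss only, dropout 0.3, up to 500 epochs with early stopping
  on validation loss (default patience 25); the best-validation parameters
  are restored. One integer seed drives initialisation, shuffling and
  dropout masks, so runs are bit-reproducible. Hidden size, dropout,
  learning rate, batch size and patience are judgment defaults, exposed in
  `TrainConfig`.
* **Initial states** h₀ = c₀ = 0 per layer.

The forward pass retains every gate activation, candidate pre-activation,
cell and hidden state per step and layer (`LSTMTrace`), which is what makes
exact relevance propagation possible. An independently written reference
unroll in the test suite checks logit equivalence to 1e-5 at full size.

## Relevance propagation

Attribution starts from the *pre-calibration* logit y with R(y) = y and
applies, backward through the trace:

1. **Head (ε-rule).** R(h_k) = h_k·ω_k / (y + ε·sign(y)) · R(y), with the
   batch-norm affine folded into effective head weights ω.
2. **Hidden → cell.** R(c_t) = R(h_t) ⊙ o_t ⊙ (1 − tanh²c_t), following
   ∂h_t/∂c_t.
3. **Cell split.** R(c_t) — which also accumulates the forget-branch share
   forwarded from step t+1 — is divided between f_t⊙c_{t−1} (sent to step
   t−1) and i_t⊙g_t in proportion to the branches' magnitudes,
   ε-stabilised.
4. **Candidate gating.** R(g_t) = R(i⊙g) ⊙ i_t.
5. **Candidate pre-activation (ε-rule).** R(g_t) is redistributed over the
   concatenated input [h_{t−1}, x_t] using the candidate weights and the
   bias-inclusive pre-activation, incrementing R(h_{t−1}) (continuing the
   recursion through time) and R(x_t).

In a stacked model, relevance assigned to layer l's input at step t is
added to layer l−1's hidden-state relevance at the same step and re-enters
that layer's recursion; layer-1 input relevance is the output, a signed
6 × 66 map per window. Zero initial states receive no relevance.

Only the candidate pathway carries relevance for new information; the
input, forget and output gates are treated as regulators. Two of the rules
rescale rather than conserve relevance: step 2 multiplies by
o⊙(1 − tanh²c), and step 4 multiplies by i. Conservation therefore holds
per ε-rule application (exactly, at ε = 0, up to bias leakage) but not
across a whole backward pass. The rules are implemented exactly as stated
above; a strict-conservation variant (cell relevance passed through
unscaled in step 2) is available behind a flag for comparison. Bias terms
absorb relevance implicitly — numerators use input contributions a_jω_j
while denominators are bias-inclusive — and the resulting per-window
leakage is reported as a diagnostic.

Numerical conventions: ε defaults to 1e-3 (configurable; maps converge as
ε → 0, which a test checks over 1e-1…1e-4); sign(0) := +1; dropout is
inactive at explanation time.

Cohort-level importance aggregates per-(feature, epoch) means over windows
and, per feature, both the signed sum over epochs and the mean absolute
per-window aggregate. Both are emitted because signed means cancel when a
feature pushes different windows in different directions.

**Interpretation caveat.** Because relevance is proportional to activation
× weight, features with large, nearly constant scaled activations (vital
sign levels hover near mid-range) accumulate a near-constant "offset"
relevance that reflects baseline throughput, not discrimination. On
synthetic cohorts this shows up as vital-sign statistics ranking near
genuinely predictive features; their per-window relevance barely varies,
whereas a true driver's relevance tracks the prediction. Permutation
validation and occlusion (both implemented) disambiguate the two, and the
test suite requires them to agree with the attribution ranking.

## Calibration and evaluation

Platt scaling fits an (effectively unregularised) one-dimensional logistic
regression of the validation labels on the logit of the raw score:
p_cal = σ(A·logit(p_raw) + B), with raw scores clipped to
[1e-7, 1 − 1e-7] before the logit. For A > 0 the map is strictly monotone,
so AUROC/AUPRC are invariant — a property the tests assert exactly.
Fixed-sensitivity rows use the largest threshold whose sensitivity reaches
the target (samples at or above the threshold are positive), over the grid
{0.70, 0.75, 0.80, 0.85, 0.90, 0.95}; evaluation is reported on calibrated
scores by default (rank metrics are unaffected; thresholds differ), with a
raw-score option. ECE uses 10 equal-width bins, empty bins skipped. The
size of the validation split used for calibration is a pipeline parameter
(default 20% of training patients), since nothing in the problem pins it.

Permutation validation operates on the scaled matrices the model consumes,
with raw outputs thresholded at 0.5. "Shuffling across the observation
window" is read as *between-window* trajectory permutation — the feature's
six-epoch block moves between samples, preserving its within-window
temporal shape and marginal distribution while severing the link to the
label; a within-window (across-epoch) mode is provided as an option since
the phrasing admits both readings. Labels are never permuted.

## Synthetic cohort

The generator emulates the *structure* of post-extubation PICU records,
not their clinical content: irregular vital-sign sampling (Poisson, ~4
measurements per epoch) around age-banded baselines with per-epoch
missingness matching reported rates (respiratory rate 0.16% … MAP 17.19%);
per-kg tapering medication schedules with exposure probabilities following
the development-cohort profile; per-epoch WAT-1 scores consistent with the
planted labels. Age-band frequencies follow the development cohort; the
band-level vital norms and weight-for-age curve are generator constants,
not clinical reference values.

Labels come from a planted per-epoch logistic mechanism using only
information preceding the epoch: the count of positive epochs in the
recent history window (saturable; by default the window and saturation
exceed the stay length, giving simple self-exciting escalation), the
patient's documented pre-ICU withdrawal-episode count (Poisson, mean 0.6,
saturating at 3 episodes), a recency-weighted heart-rate max-delta
z-score, scaled cumulative fentanyl and morphine doses, and midazolam
exposure epochs, plus Gaussian logit noise. An optional remission term
(off by default) damps sustained runs so episodes can resolve.

The reference (default) configuration makes withdrawal history dominant
(in-stay escalation 3.0 and prior-history 1.2 per episode, versus
0.45/0.35/0.25/0.15 for the secondary terms) over short monitored stays of
7–14 epochs (28–56 h after extubation). Three choices here are deliberate
and coupled. Clinically, withdrawal episodes strongly beget further
episodes and documented prior withdrawal is a leading risk factor.
Methodologically, attribution-recovery tests need the driver feature's
*scaled* activation to be substantial: min-max scaling divides the raw
count by its training maximum, so long stays with unbounded escalation
produce a heavy-tailed count whose typical scaled value collapses toward
zero, and the prior-history component gives the feature between-patient
signal even in windows from patients with no in-stay episode yet. Short
stays bound the count's range; history dominance keeps the driver
unambiguous.

Two sibling presets serve designed experiments: `recency_config` plants
the signal entirely in the most recent epoch's heart-rate variability (for
recency tests), and `graded_config` uses five well-separated, individually
learnable coefficients (for dose-response checks: permutation-drop
ordering and coefficient-sign recovery, which are unidentifiable under the
deliberately lopsided default); both use 30-epoch stays and no
prior-history effect. Intercepts are tuned by bisection (`tune_intercept`)
to a target prediction-epoch prevalence of 0.23; realized prevalence at a
fixed intercept varies between cohort seeds with a standard deviation of
roughly 0.01 at 2,000 patients because labels cluster within patients.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: pharmacokinetics (doses taper on a schedule
rather than responding to patient state), correlated multi-organ
physiology (vitals are independent given the age band, except that
heart-rate variability feeds risk), informative missingness,
measurement error in WAT-1 scoring, or inter-rater variability. Ground
truth (per-epoch probabilities, covariates, coefficient vector, driver
ranking) is returned alongside every cohort for recovery tests.

## Problem sizes

The test suite and the acceptance script run scaled-down versions of the
reference experiments: 300-patient cohorts (≈3,600 windows) for end-to-end
discrimination, permutation and calibration checks, 500 patients for
attribution-driver recovery across training seeds, 1,000–2,000 patients
for generator-level statistical checks (prevalence control, sign
recovery), and training schedules of 150–400 epochs with early-stopping
patience 20–60. These sizes were chosen so the full suite completes in
minutes on one CPU while leaving the planted effects comfortably above
sampling noise.

## Known limitations

* The candidate-only relevance rules are not globally conservation-
  preserving (by construction); relevance magnitudes are comparable within
  a model but not across models.
* Min-max scaling is sensitive to training-range outliers; robust scaling
  is out of scope.
* The permutation report treats windows as exchangeable; within-patient
  correlation between overlapping windows is ignored (as it is in the
  sliding-window training itself).
* No bootstrap confidence intervals on metrics; single-split evaluation.
* The serialized model bundle stores parameters only; retraining state
  (optimizer moments) is not checkpointed.
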