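# iwsrisk

Explainable LSTM risk prediction for **iatrogenic withdrawal syndrome (IWS)**
in pediatric intensive care.

Children who receive opioids and sedatives for prolonged periods in the ICU
frequently develop withdrawal when those medications are weaned — a condition
screened at the bedside with the WAT-1 scale (an 11-item, 12-point score;
WAT-1 ≥ 3 indicates withdrawal). `iwsrisk` implements a complete, tested
pipeline for *dynamic* withdrawal-risk prediction from longitudinal
electronic-health-record data: given the preceding 24 hours of a patient's
vital signs, medication administrations and withdrawal history, it estimates
the probability that withdrawal is observed in the next 4 hours — and explains
each prediction feature-by-feature and epoch-by-epoch.

The package is aimed at methods researchers in clinical time-series modelling:
every stage is a plain Python API with a thin CLI, and a synthetic cohort
generator with a *known, planted* risk mechanism makes the whole chain —
feature extraction, training, attribution, validation — testable end to end
without access to protected health data.

## What is inside

* **`iwsrisk.features`** — epoch-based featureization. The post-extubation
  timeline is cut into 4-hour epochs; each epoch becomes a 66-feature vector
  (6 vitals × {min, max, max-delta, mean, count}, 8 drugs ×
  {epoch dose rate/kg, cumulative dose/kg, previous-epoch dose/kg, cumulative
  exposure duration}, plus age, prior withdrawal-epoch count, epoch index,
  ventilation duration). Six consecutive epochs form an observation window;
  the label is whether any WAT-1 ≥ 3 falls in the following epoch. Missing
  vital epochs are imputed (one-epoch carry-forward → patient mean → training-
  cohort mean) and features are min-max scaled on the training split.
* **`iwsrisk.model`** — a manually unrolled, unidirectional multilayer LSTM
  (default two layers, hidden size 64) with the standard cell

      i_t = σ(W_ih^i x_t + W_hh^i h_{t−1} + b^i)        f_t, o_t analogous
      g_t = tanh(W_ih^g x_t + W_hh^g h_{t−1} + b^g)
      c_t = f_t ⊙ c_{t−1} + i_t ⊙ g_t,   h_t = o_t ⊙ tanh(c_t)

  followed by batch norm, dropout and a fully connected head producing a
  sigmoid risk score. All weights initialise uniform on [−1/√H, 1/√H].
  Training is analytic backpropagation through time with Adam, binary
  cross-entropy, and early stopping on validation loss; every gate activation
  is retained per step for attribution.
* **`iwsrisk.lrp`** — layer-wise relevance propagation through the recurrent
  cell. The pre-calibration logit is redistributed backward through the head
  (ε-rule), into the cell state (via ∂h/∂c = o⊙(1−tanh²c)), split between the
  forget and input branches in proportion to their magnitudes, gated onto the
  candidate, and finally spread over the concatenated [h_{t−1}, x_t] by the
  ε-rule on the candidate pre-activation — recursing backward through time and
  down through layers until every feature at every epoch holds a signed
  relevance score.
* **`iwsrisk.calibration`** — Platt scaling fitted on the validation split,
  fixed-sensitivity operating-point tables (sensitivity → threshold,
  precision, accuracy, specificity, NPV, F1), ROC/PR curves with areas, and
  reliability curves with expected calibration error.
* **`iwsrisk.permutation`** — global (whole-trajectory) and epoch-specific
  permutation of single features across windows, with full metric blocks and
  deltas at threshold 0.5 on raw outputs.
* **`iwsrisk.cohort`** — the synthetic cohort generator: age-banded vitals
  with per-variable missingness (0.16%–17.2%), tapering per-kg medication
  schedules, and per-epoch WAT-1 labels drawn from a planted logistic
  mechanism (withdrawal history, recency-weighted heart-rate variability,
  cumulative opioid dose, sedative exposure) tuned to 23% prevalence.

## Worked example

A full run on a 300-patient synthetic cohort (about a minute on one CPU):

```
$ iwsrisk simulate --n-patients 300 --seed 7 --out cohort
wrote cohort of 300 patients to cohort (prediction-epoch prevalence 0.244)

$ iwsrisk prepare --vitals cohort/vitals.csv --meds cohort/meds.csv \
    --wat1 cohort/wat1.csv --patients cohort/patients.csv --seed 7 --out windows
windows: train=884 val=204 test=317

$ iwsrisk train --windows windows --seed 0 --max-epochs 150 --patience 20 --out model
trained 27 epochs (best val loss at epoch 6); saved to model

$ iwsrisk evaluate --model model --windows windows --out eval
{
  "auroc": 0.9140239605355884,
  "auprc": 0.8449139005598981,
  "ece": 0.07587756184403273,
  "calibrated": true,
  "n_test": 317
}
```

Held-out discrimination is strong (AUROC 0.91); `eval/sensitivity_table.csv`
holds the fixed-sensitivity operating points and `eval/calibration_curve.csv`
the reliability bins.

Explanation and validation:

```
$ iwsrisk explain --model model --windows windows --out relevance
            feature_name  signed_relevance  mean_abs_relevance  rank_signed  rank_abs
 prior_withdrawal_epochs          0.083402            0.083402            1         1
                 sbp_max          0.078408            0.078408            2         2
                 sbp_min         -0.062941            0.062941            3         3
   temperature_max_delta         -0.062568            0.062568            4         4
    respiratory_rate_max          0.058455            0.058455            5         5

$ iwsrisk permute --model model --windows windows \
    --feature prior_withdrawal_epochs --seed 0 --out perm.csv
       permuted_feature    auroc  delta_auroc  ...
                    N/A 0.914024          NaN  ...
prior_withdrawal_epochs 0.486711    -0.427313  ...
```

The generator plants withdrawal history — documented pre-ICU episodes plus
the accumulating count of in-stay withdrawal epochs — as the dominant risk
driver, and both diagnostics recover it: the feature tops the relevance
ranking, and shuffling its trajectory across windows collapses AUROC from
0.91 to 0.49 while permuting an uninformative feature moves it by less than
0.01. The vital-sign statistics just below it carry near-constant relevance
that reflects baseline activation rather than discrimination — see
`docs/methods.md` for why, and how permutation and occlusion disambiguate
the two.

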