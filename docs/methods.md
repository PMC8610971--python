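# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the benchmarks do and do not demonstrate.

## The prediction problem

Patients are split into an **AF group** (at least one ECG ever interpreted as
atrial fibrillation or flutter) and an **SR group** (sinus rhythm throughout).
Each patient is anchored on an *index date*: the first AF episode for the AF
group, the last recorded ECG for the SR group. Only sinus-rhythm ECGs enter
the modelling; the task is to score each record for the risk of a *future* AF
episode, and to aggregate per patient. Automatic AF interpretations from
recording machines are error-prone, so the first-AF record of every AF patient
is double-confirmed by a rhythm classifier; patients whose first-AF record
scores below 0.3 are dropped. The in-package confirmer is a small logistic
classifier on two rhythm statistics (RR coefficient of variation and detected
P waves per QRS) trained on synthetic rhythm examples — a deliberately simple
stand-in for a full deep rhythm network, adequate because synthetic AF rhythm
is grossly irregular.

Time windows (month = 30 days, year = 365 days): AF evaluation records must
fall 2 months to 1 week before the index (the final week is excluded because
imminent-AF records often come from hospitalised patients whose AF has acute
causes); AF training records are any pre-index sinus records; SR records must
predate the SR index by ≥ 2 years (so "control" records are far from any
unobserved AF). Second-phase fallbacks admit post-index sinus records (AF) and
the 1–2-year window (SR) when stratified quotas cannot be filled.

## Synthetic cohort generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a source signal,
projected to the 12 leads by a fixed 12×5 weight matrix with textbook
polarity (deep S and inverted T in V1, dominant R laterally, inverted aVR).
Defaults: P 0.15 mV / σ 22 ms centred 150 ms before R (PR interval 160 ms
from P onset at −2.5σ to QRS onset at R−45 ms), R 1.0 mV, T 0.35 mV. Records
are 10 s at 500 Hz. Noise: white (0.02 mV), baseline wander (0.05 mV at
0.25 Hz), RR jitter (2%), and per-record amplitude variability — a lognormal
record gain (σ = 0.10) and independent per-wave gains (σ = 0.08) standing in
for electrode placement and habitus. Without this variability any planted
amplitude effect is trivially separable, which is unrealistic and makes every
benchmark saturate.

**Pre-AF class effect** on sinus records of AF patients, controlled by
`delta_p ∈ [0,1]` and optionally restricted to named leads:

* P amplitude multiplied by `delta_p` ("P minimum or missing" before AF);
* PQ-segment level shifted by `pq_shift_uv · (1 − delta_p)` (default −20 µV at
  full effect);
* P duration multiplied by `1 + (p_pre_af_widening − 1)(1 − delta_p)`
  (default 1.4 at full effect) — an interatrial-block-like P prolongation,
  the classic ECG precursor of AF. The default morphology renders the
  prolonged P as two part-fused humps (the notched P of advanced interatrial
  block), peak-normalised so the shape fuses back into a single normal P as
  the effect vanishes; a single widened Gaussian is available as an
  alternative.

All three components vanish at `delta_p = 1`, so the two classes are
exchangeable by construction at the null — verified by a two-sample KS test
on detected P amplitudes.

**Age trends** (centred at 60 y): T-wave amplitude −0.8%/y (−1.5%/y in the
confound study), heart rate +0.25 bpm/y, PR +0.3 ms/y. These create the
age-correlated nuisance signal that makes control-sampling scenarios
consequential. Note a subtlety: because AF records cluster near the index
date while SR records must be ≥ 2 years older, age trends leak a small class
signal *even with identical index-age distributions*; the planted-effect and
null benchmark configurations therefore zero the age slopes, while the
confound study keeps them (they are its subject).

**Demographics** follow the clinical setting: AF ages ~ Normal(80, 8), SR
ages ~ Normal(64, 12), ~50% female, ECGs spread over a 9-year window, a few
percent of patients with missing age, single records, mislabelled first-AF
records, or missing discrete features.

## Models

All six predictors map one 12-lead record (optionally with age/100 and sex)
to a score in [0, 1]. The five networks run on the package's own numpy
reverse-mode autodiff engine; gradients of every fused primitive
(convolution, batch norm) are verified against finite differences in the test
suite.

1. **resnet** — three residual blocks (kernels 8/5/3, batch norm, ReLU, 1×1
   projection shortcut, dropout 0.3 and Gaussian noise σ 0.1 after each
   block), convolving along time only with weights shared across leads; global
   average pooling over each channel's (time, lead) map; one linear output.
2. **resnet_demo** — same trunk; pooled features → 4 aggregated features →
   concatenated with age and sex → linear output.
3. **resnet_recurrent** — same trunk; a convolution merges the lead dimension;
   max-pool 4; two stacked LSTM layers; linear head on the last state.
4. **rnn** — first 5 s only, max-pool 4 along time, two stacked LSTM layers,
   dropout, linear head.
5. **scattering_mlp** — per-lead wavelet scattering (Morlet banks, invariance
   5 s, 8 then 2 wavelets per octave; orders 0–2 with the standard
   `ξ₂ < ξ₁/2` pruning), coefficients of the 12 leads concatenated per 5-s
   interval, compressed by `log1p(100·x)`, scored by a small MLP; the record
   score is the mean of the interval scores.
6. **mlr** — logistic regression (statsmodels) on P duration, PR interval,
   mean RR, PQ level, age and sex; rows with missing features are discarded
   and reported; a ridge fallback handles separated designs. The 'distance'
   feature of the source regression model is not used.

Training: Adam (lr 1e-3), batch 32, binary cross-entropy, early stopping when
the validation loss sets no new minimum for 6 consecutive epochs, best-epoch
weights restored. Thresholds are chosen on patient-aggregated validation
scores at the sensitivity = specificity point (candidates are midpoints of
sorted unique scores; ties resolve toward higher specificity).

### Scales

The **reduced** scale — the configuration all benchmarks use — decimates
inputs to 25 Hz (anti-aliased polyphase), uses filter counts (8, 16, 16),
LSTM width 16, and max-pool 2 between residual blocks. Two exceptions: the
rnn takes 125 Hz input with LSTM width 24 (it pools raw samples without
convolving first; at 25 Hz pooling would erase the P wave, and the
raw-signal recurrence needs more state than the trunk-fed LSTM), and
attribution studies use 50 Hz without changing the trunk (see below). The **full** scale (500 Hz, filters
128/256/256, LSTM 64, no inter-block pooling) is implemented but not
exercised by the test suite. Residual-block internals and all optimiser
settings are conventional defaults, fully overridable — the architecture
descriptions pin only the block/filter/pooling structure.

## Evaluation

AUC is the tie-aware Mann–Whitney statistic; its 95% CI uses the
Hanley–McNeil closed form (DeLong behind a flag — which closed form the
clinical tables used is not stated). Sensitivity/specificity get exact
Clopper–Pearson intervals. DOR = (TP·TN)/(FP·FN) with
`exp(ln DOR ± 1.96·√(ΣT 1/cell))`; a 0.5 continuity correction applies to all
cells when any is empty, and is flagged. F1 CIs use a seeded 10,000-replicate
percentile bootstrap resampling *patients* (metrics are patient-level).
Fusion averages scores over the ECG ids scored by every model; ids missing
anywhere (e.g. MLR discards) are dropped and logged. Scores at or above the
threshold predict AF.

## Benchmarks and what they show

* **Planted effect** (`delta_p = 0.4`, identical age models, ~750 ECGs): the
  reduced resnet reaches held-out patient-level AUC ≥ 0.85; at
  `delta_p = 1` the AUC sits in the chance band. This validates the training
  loop and the null design, not clinical performance.
* **Scenario ordering** (AF ~ N(80,8) vs SR ~ N(64,12), `delta_p = 0.85`,
  T-amplitude slope 1.5%/y, 400+400 training ECGs): AUC(young SR) ≥
  AUC(random) ≥ AUC(age-balanced) with gaps ≥ 0.03 — on the fixed seed,
  0.99 / 0.89 / 0.82. The effect sizes were calibrated once to place the
  balanced scenario in a realistic 0.8 regime; the paper constrains none of
  these generator parameters.
* **Aggregation**: averaging a patient's ECG scores is no worse than
  unaggregated scoring (AUC difference ≥ −0.01).
* **Attribution** (effect on V2/V3 only, `delta_p = 0.2`, 50 Hz model): mean
  signed lead contributions rank V2/V3 top-2 for the AF target — the planted
  spatial structure is recovered. Temporally, once the maps are aligned (see
  below), the attribution mass concentrates around the first half of the QRS
  complex rather than inside the P window itself. This appears structural:
  for a P-suppression effect the positive AF-evidence pattern is "a QRS not
  preceded by a normal P", and a convolutional trunk with batch norm and
  global average pooling anchors that detection on the high-energy QRS
  complex, not on the absent or subtle P. The 50 Hz input keeps the map
  granularity near the P-wave scale; at 25 Hz with inter-block pooling the
  effective receptive field spans seconds and maps cannot localize below the
  beat.

What passing does **not** show: real pre-AF ECGs differ from these Gaussian
morphologies in ways the generator does not model (beat-to-beat morphology
dynamics, pathologies other than the planted effect, realistic noise and
artefacts), so the published real-data AUC columns are out of reach by
design; the synthetic benchmarks check *mechanisms* (confounding, windows,
aggregation, attribution direction), not clinical accuracy.

## Numerical and design choices

* Dates are integer days; ages floor-divide by 365. Age bins are half-open
  `[lo, hi)` (a 60th birthday lands in [60, 70)); `90 +` is unbounded.
* `avg_p_per_qrs ≠ 1` is tested as `|x − 1| > 0.05`. The ambiguous printed
  exclusion rule "QRS count in the rhythm group higher than the average P per
  QRS" is implemented literally as `n_qrs_rhythm > avg_p_per_qrs · n_qrs`
  behind a named predicate so it can be swapped.
* The rhythm double-confirmation applies to the first-episode record only.
* Age balancing: 1-nearest-age matching without replacement within sex,
  oldest targets first, with a 1-year caliper; pairs beyond the caliper are
  dropped (logged) so the matched distributions satisfy the median-gap ≤ 2 y
  and KS ≤ 0.1 contract. Test sets are matched on patient-level ages (SR test
  patients contribute all their eligible ECGs, which are spread over years).
* CAM alignment: 'same'-padded even kernels (size 8) delay each stage's
  output by half a sample at that stage's resolution, and pooling compounds
  the delay downstream; the upsampler compensates the accumulated group
  delay (verified by an impulse-relocalisation test, error ≤ 3 samples).
* CAM: the signed raw map feeds the lead statistics (contributions may be
  negative); the min–max [0, 1] map is for display and segment masses; a ReLU
  variant exists for conventional visuals. Grad-CAM pools the autodiff
  gradient of the logit and is verified proportional to CAM for this
  GAP + linear head. Upsampling along time is linear; leads are categorical.
  Lead contributions for the AF target are summarised over correctly
  classified AF records (absence target: correct SR records); CIs are
  t-intervals.
* Scattering coefficients are non-negative by construction (the order-0
  output is taken in modulus); tiny smoothing undershoots are clipped at 0.
* HDF5 cohort containers store a missing-day sentinel of −10⁹ (birth days are
  legitimately negative relative to the study epoch). WFDB export writes
  format-16 `.dat` at 200 ADU/mV with a plain-text `.hea`.
* Desk-scale problem sizes (hundreds of training ECGs, ≤ 10 epochs) are the
  package's tested conditions; every size is a constructor argument and the
  full-study sizes (5,337 training ECGs, 60/300 test patients) are plain
  configuration.

## Known limitations

The generator's lead projection is a fixed linear map, not a torso model; AF
rhythm is a stylised irregular-RR + f-wave caricature; discrete-feature
detection is threshold-based peak finding tuned to this generator's
morphology. The MLR feature list is a documented stand-in (the source model's
exact feature set is external to this package) and is fully configurable.
Training the full-scale models is computationally out of scope for the test
suite.
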