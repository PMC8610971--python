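# afpredict

Predicting **future atrial fibrillation (AF) from 12-lead ECGs recorded during
normal sinus rhythm**, as a tested, reusable pipeline. AF is frequently
asymptomatic until a first stroke; sinus-rhythm ECGs of patients who later
develop AF carry subtle atrial signatures (attenuated / prolonged P waves,
PQ-segment level shifts) that statistical and deep models can pick up. The
package is aimed at methodologists studying this prediction task — in
particular the role of **age confounding** (AF patients are ~16 years older
than controls on average, so a model can score well by reading age proxies off
the waveform) and of **model interpretability** (which leads and waveform
segments drive the prediction).

Because the clinical databases behind such studies are private, the package
ships a first-class synthetic cohort generator with the statistical structure
the analysis needs: two patient groups whose pre-AF sinus ECGs differ by a
controllable P-wave effect, an age gap between groups, age-correlated waveform
trends, multi-year multi-ECG patient histories, AF-rhythm records, and
exclusion-rule violations. Every stage of the analysis is testable end to end
with no data download.

## What it implements

* **`synthetic_data`** — Gaussian-bump PQRST beat model projected to the 12
  standard leads by a fixed per-wave weight matrix; planted pre-AF class
  effect (P amplitude multiplier `delta_p`, δ-scaled PQ level shift and
  interatrial-block-like P widening, optionally lead-restricted); AF rhythm
  (absent P, fibrillatory oscillation, irregular RR); registry scheduling with
  index dates, mislabelled records and missing features.
* **`preprocessing`** — zero-phase 0.7–90 Hz Butterworth band-pass plus a
  50 Hz notch (Q≈30), reflect-padded.
* **`cohort`** — AF index date = first AF-interpreted ECG, double-confirmed by
  a rhythm classifier at threshold 0.3; SR index date = last ECG; exclusion
  rules (age < 18, extrasystoles, atrial-to-ventricular ratio > 2 or < 1/2,
  P-per-QRS ≠ 1, QRS-count rule); time windows (evaluation: 2 months–1 week
  before the AF index; training: any pre-index; SR: ≥ 2 years before index;
  phase-2 fallbacks); sampling scenarios `random_sampling`, `balanced_age`
  (1-nearest-age caliper matching within sex), `young_sr`, and ten age–sex
  strata.
* **`models`** — six AF-score predictors: a 1-D residual CNN over (time, lead)
  with GAP + linear head (CAM-compatible), the same trunk with age/sex inputs,
  the trunk with a lead-merging convolution + two LSTM layers, a pooled-input
  LSTM on the first 5 s, a wavelet-scattering + MLP model (invariance 5 s,
  filter banks of 8 and 2 wavelets per octave), and a multivariate logistic
  regression on discrete waveform features. Networks run on an in-package
  numpy reverse-mode autodiff engine (`afpredict.nn`); training uses Adam,
  Gaussian input noise σ = 0.1, dropout, and patience-6 early stopping with
  best-epoch restore.
* **`evaluation`** — per-patient aggregation (average / maximum / none),
  sensitivity = specificity threshold selection on validation, AUC with
  Hanley–McNeil (or DeLong) CIs, Clopper–Pearson CIs, diagnostic odds ratio
  with log-normal CI and 0.5 continuity correction, F1 with a 10,000-replicate
  patient bootstrap, score fusion over the common ECG set, and
  misclassification age profiles.
* **`interpretability`** — CAM / Grad-CAM over (time, lead) for the resnet,
  signed per-lead mean contributions with 95% CIs per age–sex stratum, and
  importance-mass attribution over beat segments (pre-P baseline, P wave, QRS
  halves, T wave).

## Worked example

```python
from afpredict import (SimulationConfig, generate_registry,
                       assign_groups_and_index_dates, make_rhythm_confirmer,
                       SplitSizes, ModelConfig)
from afpredict.pipeline import run_experiment

config = SimulationConfig(n_af_patients=200, n_sr_patients=3000,
                          delta_p=0.85, t_amp_age_slope=0.015, seed=21)
registry = generate_registry(config)
registry, report = assign_groups_and_index_dates(registry,
                                                 make_rhythm_confirmer(0))
sizes = SplitSizes(train_af_ecgs=400, val_af_ecgs=50,
                   test_af_patients=30, test_sr_patients=60)
model = ModelConfig(architecture="resnet", max_epochs=6, seed=1)
for scenario in ("balanced_age", "random_sampling", "young_sr"):
    result = run_experiment(registry, scenario, sizes, model, seed=5)
    print(scenario, round(result.test_auc, 3))
```

prints (fixed seeds, single CPU):

```
balanced_age 0.813
random_sampling 0.883
young_sr 0.988
```

i.e. the same model family looks dramatically better or worse depending purely
on how the control group's **age distribution** is sampled — balancing ages
isolates the waveform effect (AUC 0.81), natural sampling inflates it to 0.88,
and deliberately young controls to 0.99. Patient-level reports
(`result.metrics`) add sensitivity/specificity, DOR and F1 with 95% CIs at the
validation-selected threshold.

A command-line interface mirrors the pipeline:

```bash
afpredict simulate --out cohort.h5 --seed 4
afpredict build-cohort --in cohort.h5 --scenario balanced_age --seed 1 --out split.json
afpredict run --in cohort.h5 --arch resnet --scenario random_sampling --seed 1 --out report.json
afpredict explain --in cohort.h5 --seed 1 --out cam/
```

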