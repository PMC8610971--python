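"""End-to-end assembly: registry -> splits -> model tensors -> metrics.

This is the orchestration layer the command-line interface, the test suite
and the reproduction script all share.  Signals are rendered on demand from
the registry, band-pass/notch filtered, then decimated to the model input
rate (an anti-aliased polyphase resample; the 0.7-90 Hz cleaning has already
happened at the full 500 Hz rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .cohort import (CohortSplit, Scenario, SplitSizes, build_scenario_split,
                     stratum_label)
from .evaluation import (MetricsReport, aggregate_scores, classification_metrics,
                         roc_auc_ci, select_threshold)
from .models import (DEFAULT_MLR_FEATURES, AFScore, ModelConfig, ModelData,
                     build_model, fit_mlr, predict_scores, train)
from .preprocessing import FilterSpec, preprocess_signals
from .synthetic_data import ConfigurationError, Registry, realize_signals


def assemble_model_data(registry: Registry, items, config: ModelConfig,
                        filter_spec: FilterSpec | None = None) -> ModelData:
    """Render, filter and decimate the signals of the listed split items."""
    fs_in = registry.config.sampling_rate
    down = fs_in / config.input_fs
    if abs(down - round(down)) > 1e-9 or down < 1:
        raise ConfigurationError(
            f"input_fs {config.input_fs} must divide the recording rate {fs_in}")
    down = int(round(down))
    X, y, age, sex, ecg_ids, patient_ids, feat_rows = [], [], [], [], [], [], []
    for ecg_id, patient_id, label in items:
        rec = realize_signals(registry.ecgs[ecg_id], registry)
        patient = registry.patients[patient_id]
        sig = preprocess_signals(rec.signals, fs_in, filter_spec)
        if down > 1:
            sig = resample_poly(sig, 1, down, axis=-1)
        X.append(sig.astype(np.float32))
        y.append(1.0 if label == "AF" else 0.0)
        a = patient.age_on(rec.acquisition_day)
        age.append(np.nan if a is None else float(a))
        sex.append(1.0 if patient.sex == "F" else 0.0)
        ecg_ids.append(ecg_id)
        patient_ids.append(patient_id)
        d = rec.discrete
        row = {}
        for name in DEFAULT_MLR_FEATURES:
            if name == "sex":
                row[name] = sex[-1]
            elif name == "age_years":
                row[name] = age[-1]
            else:
                v = getattr(d, name) if d is not None else None
                row[name] = np.nan if v is None else float(v)
        feat_rows.append(row)
    return ModelData(X=np.stack(X) if X else np.zeros((0, 12, 0), np.float32),
                     y=np.array(y, np.float32), age=np.array(age),
                     sex=np.array(sex), ecg_ids=ecg_ids,
                     patient_ids=patient_ids, fs=float(config.input_fs),
                     features=pd.DataFrame(feat_rows))


@dataclass
class ExperimentResult:
    split: CohortSplit
    model: object
    history: object | None
    threshold: float
    rule: str
    ecg_scores: list[AFScore]
    patient_scores: list
    patient_labels: np.ndarray
    patient_ids: list[str]
    patient_ages: np.ndarray
    test_auc: float
    test_auc_ci: tuple[float, float]
    metrics: MetricsReport
    test_data: ModelData | None = None
    extras: dict = field(default_factory=dict)


def patient_level(scores, data: ModelData, rule: str):
    """Aggregate ECG scores to patients; returns (pscores, labels, ids, ages)."""
    e2p = dict(zip(data.ecg_ids, data.patient_ids))
    pscores = aggregate_scores(scores, e2p, rule)
    label_by_pid, age_by_pid = {}, {}
    for i, pid in enumerate(data.patient_ids):
        label_by_pid[pid] = int(data.y[i])
        age_by_pid[pid] = data.age[i]
    labels = np.array([label_by_pid[s.patient_id] for s in pscores])
    ages = np.array([age_by_pid[s.patient_id] for s in pscores])
    return pscores, labels, [s.patient_id for s in pscores], ages


def run_experiment(registry: Registry, scenario: Scenario | str,
                   sizes: SplitSizes, model_config: ModelConfig, seed: int = 0,
                   rule: str = "avg", phase: int = 1,
                   keep_test_data: bool = False,
                   split: CohortSplit | None = None) -> ExperimentResult:
    """Train one model under one scenario and evaluate it patient-level.

    The decision threshold is selected on patient-aggregated validation
    scores at the point where sensitivity equals specificity, then frozen for
    the test set.
    """
    if split is None:
        split = build_scenario_split(registry, scenario, sizes, seed=seed,
                                     phase=phase)
    cfg = model_config.replace(seed=seed)
    train_data = assemble_model_data(registry, split.train, cfg)
    val_data = assemble_model_data(registry, split.val, cfg)
    test_data = assemble_model_data(registry, split.test, cfg)

    if cfg.architecture == "mlr":
        model = fit_mlr(train_data.features, train_data.y, cfg.mlr_features)
        history = None
    else:
        n_coeffs = None
        if cfg.architecture == "scattering_mlp":
            from .models import ensure_scattering

            n_coeffs = ensure_scattering(train_data, cfg).shape[-1]
        model = build_model(cfg, n_scattering_coeffs=n_coeffs)
        history = train(model, train_data, val_data, cfg)

    val_scores, _ = predict_scores(model, val_data)
    vps, vlabels, _, _ = patient_level(val_scores, val_data, rule)
    threshold = select_threshold([s.score for s in vps], vlabels)

    ecg_scores, _ = predict_scores(model, test_data)
    pscores, plabels, pids, pages = patient_level(ecg_scores, test_data, rule)
    values = [s.score for s in pscores]
    auc, auc_ci = roc_auc_ci(values, plabels)
    metrics = classification_metrics(values, plabels, threshold, seed=seed)
    return ExperimentResult(
        split=split, model=model, history=history, threshold=threshold,
        rule=rule, ecg_scores=ecg_scores, patient_scores=pscores,
        patient_labels=plabels, patient_ids=pids, patient_ages=pages,
        test_auc=auc, test_auc_ci=auc_ci, metrics=metrics,
        test_data=test_data if keep_test_data else None,
        extras={"registry": registry} if keep_test_data else {})


def test_strata(registry: Registry, result: ExperimentResult) -> list[str]:
    """Age-sex stratum label of each aggregated test patient (age at index)."""
    out = []
    for pid in result.patient_ids:
        p = registry.patients[pid]
        out.append(stratum_label(p.age_on(p.index_day), p.sex))
    return out
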