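"""Patient-level aggregation, thresholding, metrics with CIs, model fusion.

Test sets contain several ECGs per patient; per-ECG AF scores are reduced to
one value per patient by the average or the maximum rule (or left unaggregated
with the ``all`` rule).  The decision threshold is chosen on the validation
set where sensitivity equals specificity.  Metrics follow standard diagnostic
conventions:

* AUC — tie-aware Mann-Whitney statistic; 95% CI by the Hanley-McNeil closed
  form (DeLong available behind a flag);
* sensitivity / specificity — exact (Clopper-Pearson) binomial 95% CIs;
* diagnostic odds ratio — DOR = (TP.TN)/(FP.FN) with the log-normal CI
  exp(ln DOR +- 1.96 sqrt(1/TP + 1/FP + 1/FN + 1/TN)), 0.5 added to every
  cell when any cell is empty;
* F1 — 2TP/(2TP + FP + FN) with a seeded percentile bootstrap over patients
  (10,000 replications).

Fusion averages the per-ECG scores of the individual models over the ECG ids
scored by all of them (ids missing from any model, e.g. the MLR discards, are
dropped and logged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .models import AFScore
from .synthetic_data import ConfigurationError


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    rule: str                 # {"avg", "max", "all"}
    score: float


@dataclass
class MetricsReport:
    n_pos: int
    n_neg: int
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float | None
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    dor: float
    dor_ci: tuple[float, float]
    dor_corrected: bool
    f1: float
    f1_ci: tuple[float, float] | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity, "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity, "specificity_ci": list(self.specificity_ci),
            "dor": self.dor, "dor_ci": list(self.dor_ci),
            "dor_corrected": self.dor_corrected,
            "f1": self.f1, "f1_ci": list(self.f1_ci) if self.f1_ci else None,
            "auc": self.auc, "auc_ci": list(self.auc_ci) if self.auc_ci else None,
        }


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_scores(scores: Sequence[AFScore],
                     ecg_to_patient: Mapping[str, str],
                     rule: str = "avg") -> list[PatientScore]:
    """Reduce per-ECG scores to per-patient scores under the named rule."""
    if rule not in ("avg", "max", "all"):
        raise ConfigurationError(f"unknown aggregation rule {rule!r}")
    if rule == "all":
        return [PatientScore(ecg_to_patient[s.ecg_id], "all", s.score)
                for s in scores]
    per_patient: dict[str, list[float]] = {}
    for s in scores:
        per_patient.setdefault(ecg_to_patient[s.ecg_id], []).append(s.score)
    reducer = np.mean if rule == "avg" else np.max
    return [PatientScore(pid, rule, float(reducer(vals)))
            for pid, vals in per_patient.items()]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ConfigurationError("both classes must be present")


def roc_auc_ci(scores, labels, method: str = "hanley-mcneil"
               ) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a closed-form 95% CI, clipped to [0, 1]."""
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    auc = float(roc_auc_score(labels, scores))
    n1 = int((labels == 1).sum())
    n2 = int((labels == 0).sum())
    if method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc * auc / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc * auc)
               + (n2 - 1) * (q2 - auc * auc)) / (n1 * n2)
        se = np.sqrt(max(var, 0.0))
    elif method == "delong":
        se = _delong_se(scores, labels)
    else:
        raise ConfigurationError(f"unknown AUC CI method {method!r}")
    lo = float(np.clip(auc - 1.96 * se, 0.0, 1.0))
    hi = float(np.clip(auc + 1.96 * se, 0.0, 1.0))
    return auc, (lo, hi)


def _delong_se(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def select_threshold(validation_scores, validation_labels) -> float:
    """Threshold where validation sensitivity and specificity are equal.

    Candidates are midpoints between consecutive sorted unique scores (plus
    one candidate below and above the score range); the candidate minimising
    |sensitivity - specificity| wins, ties broken toward higher specificity
    (the larger threshold).
    """
    scores = np.asarray(validation_scores, dtype=float)
    labels = np.asarray(validation_labels, dtype=int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1e-6], mids, [uniq[-1] + 1e-6]])
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best_thr, best_gap, best_spec = None, None, None
    for thr in candidates:
        sens = float(np.mean(pos >= thr))
        spec = float(np.mean(neg < thr))
        gap = abs(sens - spec)
        if (best_gap is None or gap < best_gap - 1e-12
                or (abs(gap - best_gap) <= 1e-12 and spec > best_spec)):
            best_thr, best_gap, best_spec = float(thr), gap, spec
    return best_thr


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return (float(lo), float(hi))


def dor_with_ci(tp: int, fp: int, fn: int, tn: int
                ) -> tuple[float, tuple[float, float], bool]:
    """Diagnostic odds ratio with the log-normal 95% CI.

    Any empty cell triggers the 0.5 continuity correction on all four cells,
    reported through the returned flag.
    """
    corrected = min(tp, fp, fn, tn) == 0
    a, b, c, d = ((tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5) if corrected
                  else (tp, fp, fn, tn))
    dor = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(dor * np.exp(-1.96 * se)), float(dor * np.exp(1.96 * se)))
    return float(dor), ci, corrected


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def metrics_from_counts(tp: int, fn: int, fp: int, tn: int,
                        threshold: float | None = None) -> MetricsReport:
    """Metrics derivable from a confusion matrix alone (no bootstrap CI)."""
    n_pos, n_neg = tp + fn, fp + tn
    sens = tp / n_pos if n_pos else 0.0
    spec = tn / n_neg if n_neg else 0.0
    dor, dor_ci, corrected = dor_with_ci(tp, fp, fn, tn)
    return MetricsReport(
        n_pos=n_pos, n_neg=n_neg, tp=tp, fp=fp, fn=fn, tn=tn,
        threshold=threshold,
        sensitivity=sens, sensitivity_ci=_clopper_pearson(tp, n_pos),
        specificity=spec, specificity_ci=_clopper_pearson(tn, n_neg),
        dor=dor, dor_ci=dor_ci, dor_corrected=corrected,
        f1=f1_from_counts(tp, fp, fn), f1_ci=None)


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      n_pos: int, n_neg: int) -> tuple[int, int, int, int]:
    """Reconstruct (tp, fn, fp, tn) from printed percentage rates and set sizes."""
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return tp, n_pos - tp, n_neg - tn, tn


def classification_metrics(patient_scores, labels, threshold: float,
                           n_bootstrap: int = 10_000,
                           seed: int = 0) -> MetricsReport:
    """Full patient-level metrics at a pre-selected threshold.

    Scores at or above the threshold predict AF.  The F1 CI is a percentile
    bootstrap resampling patients (metrics are patient-level quantities).
    """
    scores = np.asarray([s.score if isinstance(s, PatientScore) else s
                         for s in patient_scores], dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    report = metrics_from_counts(tp, fn, fp, tn, threshold=threshold)

    # bootstrap F1 over patients
    rng = np.random.default_rng(seed)
    n = len(scores)
    is_tp = (pred & (labels == 1)).astype(np.int64)
    is_fp = (pred & (labels == 0)).astype(np.int64)
    is_fn = (~pred & (labels == 1)).astype(np.int64)
    reps = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        btp, bfp, bfn = is_tp[idx].sum(), is_fp[idx].sum(), is_fn[idx].sum()
        reps[b] = f1_from_counts(btp, bfp, bfn)
    report.f1_ci = (float(np.percentile(reps, 2.5)),
                    float(np.percentile(reps, 97.5)))
    try:
        auc, ci = roc_auc_ci(scores, labels)
        report.auc, report.auc_ci = auc, ci
    except ConfigurationError:
        pass
    return report


# ---------------------------------------------------------------------------
# fusion and error profiles
# ---------------------------------------------------------------------------

def fuse(score_tables: Mapping[str, Sequence[AFScore]]
         ) -> tuple[list[AFScore], list[str]]:
    """Average the models' scores per ECG over the common id set.

    Returns the fused scores plus the ids dropped because at least one model
    did not score them.
    """
    per_model = {m: {s.ecg_id: s.score for s in table}
                 for m, table in score_tables.items()}
    common = set.intersection(*(set(d) for d in per_model.values()))
    if not common:
        raise ConfigurationError("no ECG id scored by every model")
    everything = set.union(*(set(d) for d in per_model.values()))
    dropped = sorted(everything - common)
    fused = [AFScore(ecg_id=e, model_id="fusion",
                     score=float(np.mean([d[e] for d in per_model.values()])))
             for e in sorted(common)]
    return fused, dropped


@dataclass
class MisclassificationAges:
    mean_fn_age: float | None
    n_fn: int
    mean_fp_age: float | None
    n_fp: int
    empty: bool = field(default=False)


def misclassification_age_profile(patient_scores, labels, threshold: float,
                                  ages) -> MisclassificationAges:
    """Mean ages of false negatives and false positives at the threshold."""
    scores = np.asarray([s.score if isinstance(s, PatientScore) else s
                         for s in patient_scores], dtype=float)
    labels = np.asarray(labels, dtype=int)
    ages = np.asarray(ages, dtype=float)
    pred = scores >= threshold
    fn_mask = ~pred & (labels == 1)
    fp_mask = pred & (labels == 0)
    n_fn, n_fp = int(fn_mask.sum()), int(fp_mask.sum())
    return MisclassificationAges(
        mean_fn_age=float(np.mean(ages[fn_mask])) if n_fn else None, n_fn=n_fn,
        mean_fp_age=float(np.mean(ages[fp_mask])) if n_fp else None, n_fp=n_fp,
        empty=(n_fn == 0 and n_fp == 0))
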