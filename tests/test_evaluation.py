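"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afpredict.evaluation import (AFScore, aggregate_scores,
                                  classification_metrics, dor_with_ci,
                                  counts_from_rates, f1_from_counts, fuse,
                                  metrics_from_counts,
                                  misclassification_age_profile, roc_auc_ci,
                                  select_threshold)
from afpredict.synthetic_data import ConfigurationError


def _scores(vals, model="m"):
    return [AFScore(ecg_id=f"E{i}", model_id=model, score=v)
            for i, v in enumerate(vals)]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregation_rules():
    scores = _scores([0.2, 0.8, 0.4])
    e2p = {"E0": "P1", "E1": "P1", "E2": "P2"}
    avg = {s.patient_id: s.score for s in aggregate_scores(scores, e2p, "avg")}
    mx = {s.patient_id: s.score for s in aggregate_scores(scores, e2p, "max")}
    assert avg["P1"] == pytest.approx(0.5) and mx["P1"] == pytest.approx(0.8)
    # single-ECG patient: identical under every rule
    assert avg["P2"] == mx["P2"] == pytest.approx(0.4)
    assert len(aggregate_scores(scores, e2p, "all")) == 3
    assert aggregate_scores([], {}, "avg") == []


@given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
@settings(max_examples=50, deadline=None)
def test_avg_never_exceeds_max(vals):
    scores = _scores(vals)
    e2p = {s.ecg_id: "P1" for s in scores}
    avg = aggregate_scores(scores, e2p, "avg")[0].score
    mx = aggregate_scores(scores, e2p, "max")[0].score
    assert avg <= mx + 1e-12


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _auc_by_enumeration(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    scores = [0.9, 0.6, 0.7, 0.1]
    labels = [1, 1, 0, 0]
    auc, _ = roc_auc_ci(scores, labels)
    assert auc == pytest.approx(0.75)        # 3 of 4 pairs concordant


def test_auc_perfect_separation():
    auc, ci = roc_auc_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0 and ci[1] == 1.0


def test_auc_matches_pairwise_enumeration(rng):
    for trial in range(20):
        n = int(rng.integers(4, 25))
        scores = np.round(rng.random(n), 2)  # duplicates exercise tie handling
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        auc, _ = roc_auc_ci(scores, labels)
        assert auc == pytest.approx(_auc_by_enumeration(scores, labels))


def test_auc_null_simulation(rng):
    scores = rng.random(2000)
    labels = rng.integers(0, 2, 2000)
    auc, _ = roc_auc_ci(scores, labels)
    assert 0.47 <= auc <= 0.53


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.random(200)
    labels = rng.integers(0, 2, 200)
    a1, _ = roc_auc_ci(scores, labels)
    a2, _ = roc_auc_ci(np.exp(3 * scores) - 1, labels)
    assert a1 == pytest.approx(a2)


def test_auc_one_class_rejected():
    with pytest.raises(ConfigurationError):
        roc_auc_ci([0.1, 0.2], [1, 1])


def test_delong_flag_available(rng):
    scores = rng.random(100)
    labels = rng.integers(0, 2, 100)
    auc_hm, ci_hm = roc_auc_ci(scores, labels, method="hanley-mcneil")
    auc_dl, ci_dl = roc_auc_ci(scores, labels, method="delong")
    assert auc_hm == auc_dl
    assert ci_dl[0] <= auc_dl <= ci_dl[1]


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def test_threshold_separable_case():
    scores = [0.9, 0.92, 0.88, 0.1, 0.12, 0.08]
    labels = [1, 1, 1, 0, 0, 0]
    thr = select_threshold(scores, labels)
    assert 0.12 < thr < 0.88
    pos = np.array(scores[:3])
    neg = np.array(scores[3:])
    assert np.mean(pos >= thr) == 1.0 and np.mean(neg < thr) == 1.0


def test_threshold_symmetric_gaussians(rng):
    pos = rng.normal(0.6, 0.1, 2500)
    neg = rng.normal(0.4, 0.1, 2500)
    thr = select_threshold(np.concatenate([pos, neg]),
                           np.array([1] * 2500 + [0] * 2500))
    assert abs(thr - 0.5) <= 0.02


def test_threshold_minimises_sens_spec_gap(rng):
    scores = rng.random(60)
    labels = rng.integers(0, 2, 60)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    thr = select_threshold(scores, labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best_gap = abs(np.mean(pos >= thr) - np.mean(neg < thr))
    uniq = np.unique(scores)
    for cand in (uniq[:-1] + uniq[1:]) / 2:
        gap = abs(np.mean(pos >= cand) - np.mean(neg < cand))
        assert best_gap <= gap + 1e-12


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

def _brute_force_metrics(scores, labels, thr):
    tp = fp = fn = tn = 0
    for s, l in zip(scores, labels):
        pred = s >= thr
        if pred and l == 1:
            tp += 1
        elif pred and l == 0:
            fp += 1
        elif not pred and l == 1:
            fn += 1
        else:
            tn += 1
    dor = (tp * tn) / (fp * fn) if min(tp, fp, fn, tn) > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn)
    return tp, fp, fn, tn, dor, f1


def test_metrics_match_brute_force_confusion_counting(rng):
    for trial in range(10):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        thr = float(rng.random())
        report = classification_metrics(scores, labels, thr, n_bootstrap=100,
                                        seed=trial)
        tp, fp, fn, tn, dor, f1 = _brute_force_metrics(scores, labels, thr)
        assert (report.tp, report.fp, report.fn, report.tn) == (tp, fp, fn, tn)
        assert report.f1 == pytest.approx(f1)
        if dor is not None:
            assert report.dor == pytest.approx(dor)
            assert not report.dor_corrected


def test_symmetric_counts_give_unit_dor():
    report = metrics_from_counts(tp=10, fn=10, fp=10, tn=10)
    assert report.sensitivity == 0.5 and report.specificity == 0.5
    assert report.dor == pytest.approx(1.0)


def test_zero_cell_triggers_continuity_correction():
    dor, ci, corrected = dor_with_ci(tp=10, fp=0, fn=5, tn=20)
    assert corrected
    assert dor == pytest.approx((10.5 * 20.5) / (0.5 * 5.5))
    assert ci[0] < dor < ci[1]


def test_clopper_pearson_bounds():
    report = metrics_from_counts(tp=39, fn=21, fp=88, tn=212)
    lo, hi = report.sensitivity_ci
    assert lo < report.sensitivity < hi
    assert 0.0 <= lo and hi <= 1.0
    # exact binomial at the printed precision of the clinical tables
    assert lo == pytest.approx(0.5160, abs=2e-4)
    assert hi == pytest.approx(0.7687, abs=2e-4)


def test_f1_bootstrap_deterministic_given_seed(rng):
    scores = rng.random(60)
    labels = rng.integers(0, 2, 60)
    a = classification_metrics(scores, labels, 0.5, n_bootstrap=500, seed=11)
    b = classification_metrics(scores, labels, 0.5, n_bootstrap=500, seed=11)
    assert a.f1_ci == b.f1_ci
    assert a.f1_ci[0] <= a.f1 <= a.f1_ci[1]


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def test_fusion_of_identical_tables_is_identity():
    tables = {m: _scores([0.1, 0.5, 0.9], m) for m in "abcdef"}
    fused, dropped = fuse(tables)
    assert [s.score for s in fused] == pytest.approx([0.1, 0.5, 0.9])
    assert dropped == []


def test_fusion_averages_and_drops_missing_ids():
    tables = {"a": _scores([0.2, 0.4], "a"), "b": _scores([0.8], "b")}
    fused, dropped = fuse(tables)
    assert len(fused) == 1 and fused[0].score == pytest.approx(0.5)
    assert dropped == ["E1"]


def test_fusion_empty_intersection_rejected():
    a = [AFScore("E1", "a", 0.5)]
    b = [AFScore("E2", "b", 0.5)]
    with pytest.raises(ConfigurationError):
        fuse({"a": a, "b": b})


# ---------------------------------------------------------------------------
# misclassification ages
# ---------------------------------------------------------------------------

def test_misclassification_age_profile_single_errors():
    scores = [0.9, 0.2, 0.8, 0.1]
    labels = [1, 1, 0, 0]      # FN is index 1 (70 y), FP is index 2 (85 y)
    ages = [80, 70, 85, 60]
    prof = misclassification_age_profile(scores, labels, 0.5, ages)
    assert prof.mean_fn_age == 70 and prof.mean_fp_age == 85
    assert prof.n_fn == 1 and prof.n_fp == 1 and not prof.empty


def test_misclassification_age_profile_no_errors_flagged():
    prof = misclassification_age_profile([0.9, 0.1], [1, 0], 0.5, [70, 60])
    assert prof.empty and prof.mean_fn_age is None and prof.mean_fp_age is None


def test_counts_from_rates_reconstruction():
    assert counts_from_rates(65.00, 70.67, 60, 300) == (39, 21, 88, 212)
    assert f1_from_counts(39, 88, 21) == pytest.approx(0.417, abs=1e-3)
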