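"""Index dates, exclusion rules, time windows, strata and scenario splits."""

import pytest

from afpredict.cohort import (CohortSplit, ConfirmationReport, Scenario,
                              SplitSizes, TimeWindowPolicy, apply_exclusions,
                              assign_groups_and_index_dates,
                              build_scenario_split, eligible_ecgs,
                              split_age_summary, stratify_age_sex,
                              stratum_label)
from afpredict.synthetic_data import (ConfigurationError, DiscreteFeatures,
                                      ECGRecord, Patient, Registry,
                                      SimulationConfig, generate_registry,
                                      make_violation_fixtures)


def _features(**kw):
    base = dict(age_years=50, sex="M", p_wave_duration_ms=110.0,
                pr_interval_ms=160.0, mean_rr_ms=900.0,
                pq_segment_level_uv=0.0, n_qrs=11, avg_p_per_qrs=1.0,
                av_ratio=1.0, has_extrasystoles=False, n_qrs_rhythm=11)
    base.update(kw)
    return DiscreteFeatures(**base)


def _toy_registry(af_days, af_rhythms, sr_days=None):
    """One AF patient (given ECG days/rhythms) and optionally one SR patient."""
    patients, ecgs = {}, {}
    p = Patient("A00001", "M", birth_day=-60 * 365, group="AF")
    patients[p.patient_id] = p
    for i, (day, rhythm) in enumerate(zip(af_days, af_rhythms)):
        rec = ECGRecord(ecg_id=f"EA{i}", patient_id=p.patient_id,
                        acquisition_day=day,
                        rhythm_interpretation=rhythm, discrete=_features(),
                        seed=i + 1)
        ecgs[rec.ecg_id] = rec
        p.ecg_ids.append(rec.ecg_id)
    if sr_days:
        q = Patient("S00001", "F", birth_day=-50 * 365, group="SR")
        patients[q.patient_id] = q
        for i, day in enumerate(sr_days):
            rec = ECGRecord(ecg_id=f"ES{i}", patient_id=q.patient_id,
                            acquisition_day=day,
                            rhythm_interpretation="sinus_rhythm",
                            discrete=_features(sex="F"), seed=100 + i)
            ecgs[rec.ecg_id] = rec
            q.ecg_ids.append(rec.ecg_id)
    return Registry(patients=patients, ecgs=ecgs,
                    config=SimulationConfig(noise_white_mv=0.0))


# ---------------------------------------------------------------------------
# index dates and double-confirmation
# ---------------------------------------------------------------------------

def test_af_index_is_first_confirmed_af_ecg():
    reg = _toy_registry([100, 400, 50],
                        ["atrial_fibrillation", "atrial_fibrillation",
                         "sinus_rhythm"])
    out, report = assign_groups_and_index_dates(reg, lambda rec: 0.9)
    assert out.patients["A00001"].index_day == 100
    assert report.n_checked == 1 and report.n_discarded == 0


def test_unconfirmed_first_af_discards_patient_with_log():
    reg = _toy_registry([100, 50], ["atrial_fibrillation", "sinus_rhythm"])
    out, report = assign_groups_and_index_dates(reg, lambda rec: 0.2)
    assert "A00001" not in out.patients
    assert report.n_discarded == 1
    reasons = [e for e in out.log if e.get("reason") == "unconfirmed_first_af"]
    assert reasons and reasons[0]["patient_id"] == "A00001"


def test_sr_index_is_last_ecg_date():
    reg = _toy_registry([100, 50], ["atrial_fibrillation", "sinus_rhythm"],
                        sr_days=[10, 600])
    out, _ = assign_groups_and_index_dates(reg, lambda rec: 0.9)
    assert out.patients["S00001"].index_day == 600


def test_missing_age_and_single_ecg_patients_removed():
    reg = _toy_registry([100, 50], ["atrial_fibrillation", "sinus_rhythm"],
                        sr_days=[10, 600])
    reg.patients["A00001"].birth_day = None
    single = Patient("S00002", "M", birth_day=0, group="SR")
    rec = ECGRecord(ecg_id="EX0", patient_id="S00002", acquisition_day=5,
                    rhythm_interpretation="sinus_rhythm", discrete=_features())
    reg.patients["S00002"] = single
    reg.ecgs["EX0"] = rec
    single.ecg_ids.append("EX0")
    out, _ = assign_groups_and_index_dates(reg, lambda rec: 0.9)
    assert set(out.patients) == {"S00001"}
    reasons = {e["patient_id"]: e["reason"] for e in out.log
               if e.get("event") == "patient_removed"}
    assert reasons["A00001"] == "missing_age"
    assert reasons["S00002"] == "single_ecg"


def test_confirmer_contract_enforced():
    reg = _toy_registry([100, 50], ["atrial_fibrillation", "sinus_rhythm"])
    with pytest.raises(ConfigurationError):
        assign_groups_and_index_dates(reg, lambda rec: 1.7)


def test_discard_fraction_arithmetic():
    assert ConfirmationReport(n_checked=4, n_discarded=1).discard_fraction_pct \
        == pytest.approx(25.0)


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def test_violation_fixture_set_keeps_exactly_the_clean_record():
    fixtures = make_violation_fixtures()
    kept, removed = apply_exclusions(rec for rec, _ in fixtures)
    assert len(kept) == 1 and kept[0].ecg_id == "FIX_CLEAN"
    tags = {rec.ecg_id: rules for rec, rules in removed}
    for rec, expected in fixtures:
        if expected != "none":
            assert tags[rec.ecg_id] == [expected]


@pytest.mark.parametrize("feature_overrides, rules", [
    ({"av_ratio": 0.4}, ["av_ratio_low"]),
    ({"av_ratio": 2.5}, ["av_ratio_high"]),
    ({"avg_p_per_qrs": 1.04}, []),           # within the 0.05 tolerance
    ({"avg_p_per_qrs": 1.2}, ["p_per_qrs_ne_1"]),
    # below one, the literal QRS-count rule necessarily co-fires
    ({"avg_p_per_qrs": 0.9}, ["p_per_qrs_ne_1", "qrs_rhythm_count"]),
    ({"age_years": 17}, ["age_lt_18"]),
    ({"n_qrs_rhythm": 12}, ["qrs_rhythm_count"]),
])
def test_individual_exclusion_rules(feature_overrides, rules):
    rec = ECGRecord(ecg_id="E1", patient_id="P1", acquisition_day=0,
                    rhythm_interpretation="sinus_rhythm",
                    discrete=_features(**feature_overrides))
    kept, removed = apply_exclusions([rec])
    if rules:
        assert not kept and removed[0][1] == rules
    else:
        assert kept == [rec]


def test_non_sinus_and_missing_feature_exclusions():
    af = ECGRecord(ecg_id="E1", patient_id="P1", acquisition_day=0,
                   rhythm_interpretation="atrial_fibrillation",
                   discrete=_features())
    missing = ECGRecord(ecg_id="E2", patient_id="P1", acquisition_day=0,
                        rhythm_interpretation="sinus_rhythm",
                        discrete=_features(av_ratio=None))
    kept, removed = apply_exclusions([af, missing])
    assert not kept
    assert dict((r.ecg_id, rules) for r, rules in removed) == {
        "E1": ["non_sinus"], "E2": ["missing_feature"]}


# ---------------------------------------------------------------------------
# time windows
# ---------------------------------------------------------------------------

def _windowed_patient(group, index_day, days):
    p = Patient("W1", "M", birth_day=-50 * 365, group=group,
                index_day=index_day)
    recs = [ECGRecord(ecg_id=f"W{i}", patient_id="W1", acquisition_day=d,
                      rhythm_interpretation="sinus_rhythm",
                      discrete=_features())
            for i, d in enumerate(days)]
    return p, recs


@pytest.mark.parametrize("offset, eligible", [(21, True), (3, False),
                                              (60, True), (61, False),
                                              (7, True), (6, False)])
def test_af_eval_window_two_months_to_one_week(offset, eligible):
    p, recs = _windowed_patient("AF", 1000, [1000 - offset])
    got = eligible_ecgs(p, recs, "eval", 1)
    assert bool(got) is eligible


def test_af_train_window_any_pre_index_and_phase2_fallback():
    p, recs = _windowed_patient("AF", 1000, [5, 999, 1100])
    assert [r.acquisition_day for r in eligible_ecgs(p, recs, "train", 1)] \
        == [5, 999]
    assert [r.acquisition_day for r in eligible_ecgs(p, recs, "train", 2)] \
        == [5, 999, 1100]


def test_sr_window_two_years_with_phase2_fallback():
    p, recs = _windowed_patient("SR", 1000, [1000 - 400, 1000 - 800])
    assert [r.acquisition_day for r in eligible_ecgs(p, recs, "train", 1)] \
        == [200]
    assert [r.acquisition_day for r in eligible_ecgs(p, recs, "train", 2)] \
        == [200, 600]


def test_unknown_role_rejected():
    p, recs = _windowed_patient("SR", 1000, [100])
    with pytest.raises(ConfigurationError):
        eligible_ecgs(p, recs, "holdout", 1)


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("age, sex, label", [
    (65, "M", "[60, 70)—M"),
    (60, "F", "[60, 70)—F"),     # lower boundary belongs to the upper bin
    (93, "M", "90 +—M"),
    (18, "F", "[18, 60)—F"),
    (89, "M", "[80, 90)—M"),
])
def test_stratum_labels(age, sex, label):
    assert stratum_label(age, sex) == label


def test_stratification_partitions_patients(small_registry):
    patients = list(small_registry.patients.values())
    strata = stratify_age_sex(patients)
    assert len(strata) == 10
    assigned = [p.patient_id for group in strata.values() for p in group]
    assert sorted(assigned) == sorted(p.patient_id for p in patients)


# ---------------------------------------------------------------------------
# scenario splits
# ---------------------------------------------------------------------------

SIZES = SplitSizes(train_af_ecgs=40, val_af_ecgs=10, test_af_patients=5,
                   test_sr_patients=10)


def test_split_invariants_and_determinism(small_registry):
    a = build_scenario_split(small_registry, "random_sampling", SIZES, seed=3)
    b = build_scenario_split(small_registry, "random_sampling", SIZES, seed=3)
    assert a.to_dict() == b.to_dict()
    a.check_invariants()
    ctrain = a.counts("train")
    assert ctrain["AF"] == ctrain["SR"]
    cval = a.counts("val")
    assert cval["AF"] == cval["SR"]
    # AF patients contribute at most 5 training ECGs, SR patients at most 1
    from collections import Counter

    per_patient = Counter((pid, label) for _, pid, label in a.train)
    for (pid, label), n in per_patient.items():
        assert n <= (5 if label == "AF" else 1)


def test_split_respects_time_windows(small_registry):
    split = build_scenario_split(small_registry, "random_sampling", SIZES,
                                 seed=3)
    for eid, pid, label in split.test:
        p = small_registry.patients[pid]
        day = small_registry.ecgs[eid].acquisition_day
        if label == "AF":
            assert p.index_day - 60 <= day <= p.index_day - 7
        else:
            assert day <= p.index_day - 730


def test_balanced_age_scenario_closes_the_gap():
    from afpredict.cohort import assign_groups_and_index_dates
    from afpredict.models import make_rhythm_confirmer

    # the SR pool must cover the old AF tail for 1-NN matching to close it
    registry = generate_registry(
        SimulationConfig(n_af_patients=60, n_sr_patients=2000, seed=17))
    registry, _ = assign_groups_and_index_dates(
        registry, make_rhythm_confirmer(0))
    sizes = SplitSizes(train_af_ecgs=80, val_af_ecgs=16, test_af_patients=8,
                       test_sr_patients=16)
    split = build_scenario_split(registry, "balanced_age", sizes, seed=4)
    for part in ("train", "val"):
        summary = split_age_summary(registry, split, part)
        assert abs(summary["median_af"] - summary["median_sr"]) <= 2.0
        assert summary["ks_distance"] <= 0.1
    patient = split_age_summary(registry, split, "test", patient_level=True)
    assert abs(patient["median_af"] - patient["median_sr"]) <= 2.0


def test_young_sr_scenario_separates_medians(small_registry):
    split = build_scenario_split(small_registry, "young_sr", SIZES, seed=5)
    summary = split_age_summary(small_registry, split, "train")
    assert summary["median_sr"] <= summary["median_af"] - 15.0


def test_unsatisfiable_quota_raises(small_registry):
    huge = SplitSizes(train_af_ecgs=40, val_af_ecgs=10, test_af_patients=5,
                      test_sr_patients=10_000)
    with pytest.raises(ConfigurationError):
        build_scenario_split(small_registry, "random_sampling", huge, seed=1)


def test_stratified_split_quotas_and_fallbacks(small_registry):
    from afpredict.cohort import build_stratified_split

    scenario = Scenario(name="age_sex_stratified", stratum_quota=6)
    split, test_map = build_stratified_split(
        small_registry, scenario, test_af_per_stratum=2,
        test_sr_per_stratum=2, seed=3)
    split.check_invariants()
    assert len(test_map) == 10
    # per-stratum per-class training quota respected
    from collections import Counter

    per = Counter()
    for eid, pid, label in split.train:
        p = small_registry.patients[pid]
        per[(stratum_label(p.age_on(p.index_day), p.sex), label)] += 1
    assert all(n <= 6 for n in per.values())
    # test patients never appear in train or validation
    test_pids = {pid for rows in test_map.values() for _, pid, _ in rows}
    assert not test_pids & (split.patients("train") | split.patients("val"))
    # sparse strata fall back to the widened windows, and say so
    assert any(e["event"] == "fallback_window_used" for e in split.provenance)


def test_split_roundtrip_serialisation(small_registry):
    split = build_scenario_split(small_registry, "random_sampling", SIZES,
                                 seed=3)
    again = CohortSplit.from_dict(split.to_dict())
    assert again.train == split.train and again.test == split.test
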