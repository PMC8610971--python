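"""Cohort construction: index dates, exclusions, time windows, scenario splits.

The study design anchors every patient on an index date — the first AF episode
for AF-group patients (double-confirmed by a rhythm classifier at threshold
0.3), the last recorded ECG for SR-group patients — then selects sinus-rhythm
ECGs inside role-specific time windows:

* AF evaluation: between two months and one week before the AF index (the last
  week is excluded because imminent-AF recordings often come from hospitalised
  patients with confounding acute illness);
* AF training: any time before the AF index;
* SR (all roles): at least two years before the SR index.

Second-phase fallbacks relax these when quotas cannot be met: post-index sinus
ECGs for AF patients and the one-to-two-years window for SR patients.

Scenario sampling controls the age structure of the SR side (random sampling,
age-balanced 1-nearest-age matching within sex, or deliberately young SR
patients), which is the lever the analysis uses to expose age confounding.
Calendar arithmetic uses the declared conventions month = 30 days and
year = 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .synthetic_data import (ConfigurationError, ECGRecord, Patient, Registry,
                             realize_signals)

CONFIRM_THRESHOLD = 0.3
P_PER_QRS_TOL = 0.05

AGE_BINS = ((18, 60), (60, 70), (70, 80), (80, 90), (90, None))


def stratum_label(age: float, sex: str) -> str:
    for lo, hi in AGE_BINS:
        if hi is None and age >= lo:
            return f"90 +—{sex}"
        if hi is not None and lo <= age < hi:
            return f"[{lo}, {hi})—{sex}"
    raise ValueError(f"age {age} outside the stratified range (>= 18 expected)")


@dataclass(frozen=True)
class TimeWindowPolicy:
    """Role-specific selection windows, in days before the index date."""

    eval_af_max_days: int = 60      # two months (30-day months)
    eval_af_min_days: int = 7       # last week excluded
    sr_min_days: int = 730          # at least two years before SR index
    sr_fallback_min_days: int = 365  # phase-2 window: one to two years before
    month_days: int = 30
    year_days: int = 365


@dataclass(frozen=True)
class Scenario:
    """Named SR-sampling scenario.

    ``balanced_age`` draws, for every AF ECG/patient age, the nearest-age
    unused SR patient of the same sex; ``young_sr`` restricts the SR pool to
    patients at or below ``young_max_age``; ``age_sex_stratified`` fills
    per-stratum quotas (phase 2).
    """

    name: str = "random_sampling"
    young_max_age: int = 60
    balance_tolerance_years: float = 1.0
    stratum_quota: int = 40          # ECGs per group per stratum (phase 2)

    VALID = ("random_sampling", "balanced_age", "young_sr", "age_sex_stratified")

    def __post_init__(self):
        if self.name not in self.VALID:
            raise ConfigurationError(f"unknown scenario {self.name!r}")


@dataclass(frozen=True)
class SplitSizes:
    """Desk-scale defaults; the full-study values are configurable."""

    train_af_ecgs: int = 400
    val_af_ecgs: int = 50
    test_af_patients: int = 30
    test_sr_patients: int = 60
    max_ecgs_per_af_patient: int = 5
    max_ecgs_per_sr_patient: int = 1


@dataclass
class CohortSplit:
    scenario: str
    phase: int
    train: list[tuple[str, str, str]] = field(default_factory=list)  # (ecg, patient, label)
    val: list[tuple[str, str, str]] = field(default_factory=list)
    test: list[tuple[str, str, str]] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def part(self, name: str) -> list[tuple[str, str, str]]:
        return getattr(self, name)

    def patients(self, name: str) -> set[str]:
        return {pid for _, pid, _ in self.part(name)}

    def counts(self, name: str) -> dict[str, int]:
        out = {"AF": 0, "SR": 0}
        for _, _, label in self.part(name):
            out[label] += 1
        return out

    def check_invariants(self) -> None:
        parts = [self.patients(p) for p in ("train", "val", "test")]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = parts[i] & parts[j]
                if overlap:
                    raise AssertionError(f"patient leakage across splits: {overlap}")
        for name in ("train", "val"):
            c = self.counts(name)
            if c["AF"] != c["SR"]:
                raise AssertionError(f"{name} class counts differ: {c}")

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "phase": self.phase,
                "train": self.train, "val": self.val, "test": self.test,
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSplit":
        return cls(scenario=d["scenario"], phase=d["phase"],
                   train=[tuple(x) for x in d["train"]],
                   val=[tuple(x) for x in d["val"]],
                   test=[tuple(x) for x in d["test"]],
                   provenance=d.get("provenance", []))


@dataclass
class ConfirmationReport:
    n_checked: int
    n_discarded: int

    @property
    def discard_fraction_pct(self) -> float:
        if self.n_checked == 0:
            return 0.0
        return 100.0 * self.n_discarded / self.n_checked


# ---------------------------------------------------------------------------
# index dates and rhythm double-confirmation
# ---------------------------------------------------------------------------

def assign_groups_and_index_dates(
        registry: Registry,
        rhythm_confirmer: Callable[[ECGRecord], float],
        confirm_threshold: float = CONFIRM_THRESHOLD,
) -> tuple[Registry, ConfirmationReport]:
    """Assign index dates, double-confirming each first-AF ECG.

    The confirmation score is computed for the ECG that represents the first
    episode of AF; patients whose first-AF ECG scores below the threshold are
    removed (the automatic AF interpretation is treated as unreliable).
    Patients with missing age or a single recorded ECG are removed as well.
    Returns the filtered registry plus the confirmation counts.
    """
    kept: dict[str, Patient] = {}
    n_checked = 0
    n_discarded = 0
    for patient in registry.patients.values():
        records = [registry.ecgs[e] for e in patient.ecg_ids]
        if patient.birth_day is None:
            registry.log.append({"event": "patient_removed",
                                 "patient_id": patient.patient_id,
                                 "reason": "missing_age"})
            continue
        if len(records) < 2:
            registry.log.append({"event": "patient_removed",
                                 "patient_id": patient.patient_id,
                                 "reason": "single_ecg"})
            continue
        if patient.group == "AF":
            af_recs = sorted((r for r in records
                              if r.rhythm_interpretation == "atrial_fibrillation"),
                             key=lambda r: r.acquisition_day)
            if not af_recs:
                registry.log.append({"event": "patient_removed",
                                     "patient_id": patient.patient_id,
                                     "reason": "no_af_ecg"})
                continue
            first = realize_signals(af_recs[0], registry)
            score = float(rhythm_confirmer(first))
            n_checked += 1
            if not 0.0 <= score <= 1.0:
                raise ConfigurationError(
                    f"rhythm confirmer returned {score} outside [0, 1]")
            if score < confirm_threshold:
                n_discarded += 1
                registry.log.append({"event": "patient_removed",
                                     "patient_id": patient.patient_id,
                                     "reason": "unconfirmed_first_af",
                                     "score": score})
                continue
            patient.index_day = first.acquisition_day
        else:
            patient.index_day = max(r.acquisition_day for r in records)
        kept[patient.patient_id] = patient
    out = Registry(patients=kept,
                   ecgs={e: r for e, r in registry.ecgs.items()
                         if r.patient_id in kept},
                   config=registry.config, log=registry.log)
    report = ConfirmationReport(n_checked=n_checked, n_discarded=n_discarded)
    out.log.append({"event": "confirmation_report",
                    "n_checked": n_checked, "n_discarded": n_discarded,
                    "discard_pct": report.discard_fraction_pct})
    return out, report


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

_RULE_FEATURES = {
    "age_lt_18": ("age_years",),
    "extrasystoles": ("has_extrasystoles",),
    "av_ratio_high": ("av_ratio",),
    "av_ratio_low": ("av_ratio",),
    "p_per_qrs_ne_1": ("avg_p_per_qrs",),
    "qrs_rhythm_count": ("n_qrs_rhythm", "avg_p_per_qrs", "n_qrs"),
}


def _violated_rules(rec: ECGRecord, tol: float) -> list[str] | None:
    """Rule ids violated by ``rec``; None means a required feature is missing."""
    d = rec.discrete
    if d is None:
        return None
    needed = {f for fs in _RULE_FEATURES.values() for f in fs}
    if any(d.is_missing(f) for f in needed):
        return None
    rules = []
    if d.age_years < 18:
        rules.append("age_lt_18")
    if d.has_extrasystoles:
        rules.append("extrasystoles")
    if d.av_ratio > 2:
        rules.append("av_ratio_high")
    if d.av_ratio < 0.5:
        rules.append("av_ratio_low")
    if abs(d.avg_p_per_qrs - 1.0) > tol:
        rules.append("p_per_qrs_ne_1")
    # ambiguous printed rule, implemented literally behind this predicate
    if d.n_qrs_rhythm > d.avg_p_per_qrs * d.n_qrs:
        rules.append("qrs_rhythm_count")
    return rules


def apply_exclusions(ecgs: Iterable[ECGRecord], tol: float = P_PER_QRS_TOL
                     ) -> tuple[list[ECGRecord], list[tuple[ECGRecord, list[str]]]]:
    """Keep clean sinus-interpreted ECGs; tag removals with violated rule ids."""
    kept: list[ECGRecord] = []
    removed: list[tuple[ECGRecord, list[str]]] = []
    for rec in ecgs:
        if rec.rhythm_interpretation != "sinus_rhythm":
            removed.append((rec, ["non_sinus"]))
            continue
        rules = _violated_rules(rec, tol)
        if rules is None:
            removed.append((rec, ["missing_feature"]))
        elif rules:
            removed.append((rec, rules))
        else:
            kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# time windows
# ---------------------------------------------------------------------------

def eligible_ecgs(patient: Patient, records: Sequence[ECGRecord], role: str,
                  phase: int, policy: TimeWindowPolicy | None = None
                  ) -> list[ECGRecord]:
    """Records of ``patient`` eligible for ``role`` under the window policy.

    ``records`` should already be exclusion-filtered sinus ECGs.  Phase 2
    widens the windows by the documented fallbacks (post-index sinus ECGs for
    AF training, the one-to-two-years window for SR patients).
    """
    policy = policy or TimeWindowPolicy()
    if role not in ("train", "eval"):
        raise ConfigurationError(f"unknown role {role!r}")
    if phase not in (1, 2):
        raise ConfigurationError(f"unknown phase {phase!r}")
    if patient.index_day is None:
        raise ConfigurationError(f"patient {patient.patient_id} has no index date")
    idx = patient.index_day
    out = []
    for rec in records:
        day = rec.acquisition_day
        if patient.group == "AF":
            if role == "eval":
                ok = idx - policy.eval_af_max_days <= day <= idx - policy.eval_af_min_days
            else:
                ok = day < idx or phase == 2
        else:
            ok = day <= idx - policy.sr_min_days
            if phase == 2 and not ok:
                ok = day <= idx - policy.sr_fallback_min_days
        if ok:
            out.append(rec)
    return sorted(out, key=lambda r: r.acquisition_day)


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def stratify_age_sex(patients: Iterable[Patient]) -> dict[str, list[Patient]]:
    """Partition patients into the ten age-sex strata (age at index date)."""
    strata: dict[str, list[Patient]] = {}
    for (lo, hi) in AGE_BINS:
        for sex in ("M", "F"):
            label = f"90 +—{sex}" if hi is None else f"[{lo}, {hi})—{sex}"
            strata[label] = []
    for p in patients:
        age = p.age_on(p.index_day)
        strata[stratum_label(age, p.sex)].append(p)
    return strata


# ---------------------------------------------------------------------------
# scenario splits
# ---------------------------------------------------------------------------

def _clean_sinus(registry: Registry, patient: Patient) -> list[ECGRecord]:
    kept, _ = apply_exclusions(registry.ecgs[e] for e in patient.ecg_ids)
    return kept


def _match_nearest_age(target_ages: Sequence[float], target_sexes: Sequence[str],
                       pool: list[tuple[float, str, Patient]],
                       rng: np.random.Generator, caliper: float | None = None,
                       ) -> list[tuple[Patient | None, float]]:
    """1-nearest-age sampling without replacement, within sex.

    Returns one ``(patient, age_gap)`` entry per target, in target order; a
    target whose best match exceeds the caliper gets ``(None, gap)`` so the
    caller can drop the pair (this is what keeps the matched distributions
    close when the control pool runs out of extreme ages).
    """
    out: list[tuple[Patient | None, float]] = [(None, np.inf)] * len(target_ages)
    used: set[str] = set()
    # oldest targets first: old controls are scarce and must not be spent on
    # young targets that have plenty of alternatives
    jitter = rng.random(len(target_ages))
    order = np.lexsort((jitter, -np.asarray(target_ages, dtype=float)))
    for i in order:
        age, sex = target_ages[i], target_sexes[i]
        best, best_gap = None, np.inf
        for pool_age, pool_sex, pat in pool:
            if pat.patient_id in used or pool_sex != sex:
                continue
            gap = abs(pool_age - age)
            if gap < best_gap:
                best, best_gap = pat, gap
        if best is None:  # relax the sex constraint rather than fail outright
            for pool_age, pool_sex, pat in pool:
                if pat.patient_id in used:
                    continue
                gap = abs(pool_age - age)
                if gap < best_gap:
                    best, best_gap = pat, gap
        if best is None:
            raise ConfigurationError("insufficient SR patients for age matching")
        if caliper is not None and best_gap > caliper:
            out[i] = (None, best_gap)
            continue
        used.add(best.patient_id)
        out[i] = (best, best_gap)
    return out


def build_scenario_split(registry: Registry, scenario: Scenario | str,
                         sizes: SplitSizes | None = None, seed: int = 0,
                         phase: int = 1,
                         policy: TimeWindowPolicy | None = None) -> CohortSplit:
    """Draw patient-disjoint train/validation/test sets under a scenario.

    AF patients contribute up to five training ECGs each; SR patients one.
    Training and validation are trimmed to equal per-class ECG counts; test
    sets contain every eligible ECG of the sampled test patients.
    """
    if isinstance(scenario, str):
        scenario = Scenario(name=scenario)
    sizes = sizes or SplitSizes()
    policy = policy or TimeWindowPolicy()
    rng = np.random.default_rng(seed)
    split = CohortSplit(scenario=scenario.name, phase=phase)
    log = split.provenance

    af_patients = sorted((p for p in registry.patients.values() if p.group == "AF"),
                         key=lambda p: p.patient_id)
    sr_patients = sorted((p for p in registry.patients.values() if p.group == "SR"),
                         key=lambda p: p.patient_id)

    af_eval: dict[str, list[ECGRecord]] = {}
    af_train: dict[str, list[ECGRecord]] = {}
    for p in af_patients:
        clean = _clean_sinus(registry, p)
        af_eval[p.patient_id] = eligible_ecgs(p, clean, "eval", phase, policy)
        af_train[p.patient_id] = eligible_ecgs(p, clean, "train", phase, policy)
    sr_elig: dict[str, list[ECGRecord]] = {}
    for p in sr_patients:
        clean = _clean_sinus(registry, p)
        sr_elig[p.patient_id] = eligible_ecgs(p, clean, "train", phase, policy)
    sr_pool = [p for p in sr_patients if sr_elig[p.patient_id]]

    # --- AF side -----------------------------------------------------------
    with_eval = [p for p in af_patients if af_eval[p.patient_id]]
    if len(with_eval) < sizes.test_af_patients:
        raise ConfigurationError(
            f"insufficient AF patients with evaluation-window ECGs "
            f"({len(with_eval)} < {sizes.test_af_patients})")
    test_af = list(rng.choice(with_eval, size=sizes.test_af_patients,
                              replace=False))
    test_ids = {p.patient_id for p in test_af}
    for p in test_af:
        for rec in af_eval[p.patient_id]:
            split.test.append((rec.ecg_id, p.patient_id, "AF"))

    val_candidates = [p for p in with_eval if p.patient_id not in test_ids]
    rng.shuffle(val_candidates)
    val_ids: set[str] = set()
    for p in val_candidates:
        if len(split.val) >= sizes.val_af_ecgs:
            break
        val_ids.add(p.patient_id)
        for rec in af_eval[p.patient_id][:sizes.max_ecgs_per_af_patient]:
            if len(split.val) < sizes.val_af_ecgs:
                split.val.append((rec.ecg_id, p.patient_id, "AF"))

    train_candidates = [p for p in af_patients
                        if p.patient_id not in test_ids | val_ids
                        and af_train[p.patient_id]]
    rng.shuffle(train_candidates)
    for p in train_candidates:
        if len(split.train) >= sizes.train_af_ecgs:
            break
        recs = af_train[p.patient_id]
        if len(recs) > sizes.max_ecgs_per_af_patient:
            pick = rng.choice(len(recs), size=sizes.max_ecgs_per_af_patient,
                              replace=False)
            recs = [recs[i] for i in sorted(pick)]
        for rec in recs:
            if len(split.train) < sizes.train_af_ecgs:
                split.train.append((rec.ecg_id, p.patient_id, "AF"))
    n_af_train = len(split.train)
    n_af_val = len(split.val)
    log.append({"event": "af_selected", "train": n_af_train, "val": n_af_val,
                "test_patients": len(test_af)})

    # --- SR side (scenario-specific sampling) ------------------------------
    def ecg_age(p: Patient, rec: ECGRecord) -> float:
        return p.age_on(rec.acquisition_day)

    def sr_take(patients_chosen: list[Patient], part: list, n_needed: int,
                used: set[str]) -> None:
        for p in patients_chosen:
            if len(part) >= n_needed:
                break
            if p.patient_id in used or not sr_elig[p.patient_id]:
                continue
            used.add(p.patient_id)
            rec = sr_elig[p.patient_id][-1]  # most recent eligible ECG
            part.append((rec.ecg_id, p.patient_id, "SR"))

    used_sr: set[str] = set()
    # age matching targets the age at the ECG that would actually be taken
    # (SR windows sit years before the index, so index age would be biased)
    pool_entries = [
        (float(p.age_on(sr_elig[p.patient_id][-1].acquisition_day)), p.sex, p)
        for p in sr_pool]

    if scenario.name == "young_sr":
        young = [p for p in sr_pool
                 if p.age_on(p.index_day) <= scenario.young_max_age]
        if len(young) < sizes.test_sr_patients + n_af_train + n_af_val:
            raise ConfigurationError("insufficient young SR patients")
        sampler = list(rng.permutation(young))
    else:
        sampler = list(rng.permutation(sr_pool))

    if scenario.name == "balanced_age":
        caliper = scenario.balance_tolerance_years

        def match_part(part_name: str) -> None:
            """Pair each AF ECG with a nearest-age SR patient; drop pairs
            beyond the caliper so the matched distributions stay close."""
            part = split.part(part_name)
            af_items = [it for it in part if it[2] == "AF"]
            ages = [ecg_age(registry.patients[pid], registry.ecgs[eid])
                    for eid, pid, _ in af_items]
            sexes = [registry.patients[pid].sex for _, pid, _ in af_items]
            aligned = _match_nearest_age(
                ages, sexes, [e for e in pool_entries
                              if e[2].patient_id not in used_sr],
                rng, caliper=caliper)
            kept_af, sr_new, dropped = [], [], 0
            for item, (pat, _gap) in zip(af_items, aligned):
                if pat is None:
                    dropped += 1
                    continue
                used_sr.add(pat.patient_id)
                rec = sr_elig[pat.patient_id][-1]
                kept_af.append(item)
                sr_new.append((rec.ecg_id, pat.patient_id, "SR"))
            setattr(split, part_name, kept_af + sr_new)
            if dropped:
                log.append({"event": "caliper_dropped", "part": part_name,
                            "n_pairs": dropped})

        match_part("train")
        match_part("val")

        test_age_pool = [float(p.age_on(p.index_day)) for p in test_af]
        test_sex_pool = [p.sex for p in test_af]
        draw = rng.integers(0, len(test_age_pool),
                            size=4 * sizes.test_sr_patients)
        aligned = _match_nearest_age([test_age_pool[i] for i in draw],
                                     [test_sex_pool[i] for i in draw],
                                     [e for e in pool_entries
                                      if e[2].patient_id not in used_sr],
                                     rng, caliper=caliper)
        n_taken = 0
        for pat, _gap in aligned:
            if pat is None or pat.patient_id in used_sr:
                continue
            if n_taken >= sizes.test_sr_patients:
                break
            used_sr.add(pat.patient_id)
            n_taken += 1
            for rec in sr_elig[pat.patient_id]:
                split.test.append((rec.ecg_id, pat.patient_id, "SR"))
        if n_taken < sizes.test_sr_patients:
            log.append({"event": "test_sr_short", "n": n_taken,
                        "target": sizes.test_sr_patients})
    else:
        sr_take(sampler, split.train, 2 * n_af_train, used_sr)
        sr_take(sampler, split.val, 2 * n_af_val, used_sr)
        n_test = 0
        for p in sampler:
            if n_test >= sizes.test_sr_patients:
                break
            if p.patient_id in used_sr or not sr_elig[p.patient_id]:
                continue
            used_sr.add(p.patient_id)
            n_test += 1
            for rec in sr_elig[p.patient_id]:
                split.test.append((rec.ecg_id, p.patient_id, "SR"))
        if n_test < sizes.test_sr_patients:
            raise ConfigurationError("insufficient SR patients for the test set")

    # trim AF train/val if the SR side came up short, keeping counts equal
    def trim(part: list, label: str, target: int) -> list:
        keep, n = [], 0
        for item in part:
            if item[2] == label:
                if n >= target:
                    continue
                n += 1
            keep.append(item)
        return keep

    c = split.counts("train")
    if c["SR"] < c["AF"]:
        raise ConfigurationError("insufficient SR training ECGs")
    split.train = trim(split.train, "SR", c["AF"])
    c = split.counts("val")
    split.val = trim(split.val, "SR", c["AF"])

    log.append({"event": "split_built", "scenario": scenario.name,
                "train": split.counts("train"), "val": split.counts("val"),
                "test": split.counts("test")})
    split.check_invariants()
    return split


def build_stratified_split(registry: Registry, scenario: Scenario | None = None,
                           test_af_per_stratum: int = 5,
                           test_sr_per_stratum: int = 10,
                           val_fraction: float = 0.15, seed: int = 0,
                           policy: TimeWindowPolicy | None = None
                           ) -> tuple[CohortSplit, dict[str, list]]:
    """Second-phase protocol: per-stratum quotas with documented fallbacks.

    For every age-sex stratum the training pool receives up to
    ``scenario.stratum_quota`` sinus ECGs from AF patients and as many from SR
    patients (max five per AF patient, one per SR patient).  When the primary
    time windows cannot fill a quota, the fallbacks widen them: post-index
    sinus ECGs for AF patients and the one-to-two-years window for SR
    patients.  A validation slice is carved per stratum, and each stratum
    keeps its own test set of held-out patients (all their eligible ECGs).
    Returns the pooled train/validation split plus a per-stratum test map.
    """
    scenario = scenario or Scenario(name="age_sex_stratified")
    policy = policy or TimeWindowPolicy()
    rng = np.random.default_rng(seed)
    split = CohortSplit(scenario=scenario.name, phase=2)
    test_by_stratum: dict[str, list] = {}
    strata = stratify_age_sex(registry.patients.values())
    quota = scenario.stratum_quota

    for label, patients in strata.items():
        af = [p for p in patients if p.group == "AF"]
        sr = [p for p in patients if p.group == "SR"]
        rng.shuffle(af)
        rng.shuffle(sr)

        elig: dict[str, dict[int, list[ECGRecord]]] = {}
        for p in af + sr:
            clean = _clean_sinus(registry, p)
            elig[p.patient_id] = {
                1: eligible_ecgs(p, clean, "train", 1, policy),
                2: eligible_ecgs(p, clean, "train", 2, policy)}

        test_rows: list[tuple[str, str, str]] = []
        test_ids: set[str] = set()
        for pool, n_target, label_cls in ((af, test_af_per_stratum, "AF"),
                                          (sr, test_sr_per_stratum, "SR")):
            taken = 0
            for p in pool:
                if taken >= n_target:
                    break
                recs = elig[p.patient_id][1] or elig[p.patient_id][2]
                if not recs:
                    continue
                test_ids.add(p.patient_id)
                taken += 1
                for rec in recs:
                    test_rows.append((rec.ecg_id, p.patient_id, label_cls))
        test_by_stratum[label] = test_rows

        def fill(pool, label_cls: str, per_patient: int) -> list:
            rows, phase_used = [], 1
            n_by_patient: dict[str, int] = {}
            for phase in (1, 2):
                for p in pool:
                    if len(rows) >= quota:
                        break
                    if p.patient_id in test_ids:
                        continue
                    already = {e for e, _, _ in rows}
                    recs = [r for r in elig[p.patient_id][phase]
                            if r.ecg_id not in already]
                    for rec in recs:
                        if (len(rows) >= quota or
                                n_by_patient.get(p.patient_id, 0) >= per_patient):
                            break
                        rows.append((rec.ecg_id, p.patient_id, label_cls))
                        n_by_patient[p.patient_id] = \
                            n_by_patient.get(p.patient_id, 0) + 1
                if len(rows) >= quota:
                    break
                phase_used = 2
            if phase_used == 2:
                split.provenance.append({"event": "fallback_window_used",
                                         "stratum": label, "class": label_cls,
                                         "n": len(rows)})
            return rows

        af_rows = fill(af, "AF", 5)
        sr_rows = fill(sr, "SR", 1)
        n = min(len(af_rows), len(sr_rows))
        af_rows, sr_rows = af_rows[:n], sr_rows[:n]
        n_val = max(int(round(val_fraction * n)), 1) if n else 0
        # validation takes whole patients off the tail to stay disjoint
        def carve(rows):
            val_pids: set[str] = set()
            val_rows = []
            for row in reversed(rows):
                if len(val_rows) >= n_val and row[1] not in val_pids:
                    break
                val_pids.add(row[1])
                val_rows.append(row)
            train_rows = [r for r in rows if r[1] not in val_pids]
            return train_rows, val_rows
        af_train, af_val = carve(af_rows)
        sr_train, sr_val = carve(sr_rows)
        m = min(len(af_train), len(sr_train))
        v = min(len(af_val), len(sr_val))
        split.train.extend(af_train[:m] + sr_train[:m])
        split.val.extend(af_val[:v] + sr_val[:v])
        split.provenance.append({"event": "stratum_filled", "stratum": label,
                                 "train_per_class": m, "val_per_class": v,
                                 "test_ecgs": len(test_rows)})
    split.check_invariants()
    return split, test_by_stratum


def split_age_summary(registry: Registry, split: CohortSplit,
                      part: str = "train",
                      patient_level: bool = False) -> dict[str, float]:
    """Median ages per class and the KS distance between them.

    ECG-level by default; ``patient_level`` uses each patient's age at their
    most recent included ECG (the matching basis for test sets, where SR
    patients contribute several ECGs spread over years).
    """
    ages = {"AF": [], "SR": []}
    if patient_level:
        latest: dict[str, tuple[str, int]] = {}
        for eid, pid, label in split.part(part):
            day = registry.ecgs[eid].acquisition_day
            if pid not in latest or day > latest[pid][1]:
                latest[pid] = (label, day)
        for pid, (label, day) in latest.items():
            ages[label].append(registry.patients[pid].age_on(day))
    else:
        for eid, pid, label in split.part(part):
            p = registry.patients[pid]
            ages[label].append(p.age_on(registry.ecgs[eid].acquisition_day))
    from scipy.stats import ks_2samp

    out = {"median_af": float(np.median(ages["AF"])) if ages["AF"] else np.nan,
           "median_sr": float(np.median(ages["SR"])) if ages["SR"] else np.nan}
    if ages["AF"] and ages["SR"]:
        out["ks_distance"] = float(ks_2samp(ages["AF"], ages["SR"]).statistic)
    else:
        out["ks_distance"] = np.nan
    return out
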