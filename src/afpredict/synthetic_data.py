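"""Synthetic 12-lead ECG cohorts with a controllable pre-AF signature.

The study design needs two patient groups: patients who eventually develop
atrial fibrillation (AF) and patients who stay in sinus rhythm (SR).  Real
pre-AF sinus ECGs differ from controls in subtle atrial features — the P wave
is attenuated or missing and the PQ segment level shifts — and the AF group is
markedly older (median 80 vs 64 years).  This module generates registries and
signals with exactly that statistical structure so that every downstream stage
(preprocessing, cohort windows, models, evaluation, attribution) is testable
without any clinical data.

Signal model
------------
Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) on a source signal,
projected to the 12 standard leads by a fixed 12x5 weight matrix.  The planted
class effect multiplies the P-wave amplitude of pre-AF sinus ECGs by
``delta_p`` (1 = no effect, 0 = absent P) and shifts the PQ-segment level,
optionally restricted to a subset of leads.  AF-rhythm ECGs drop the P wave,
add a fibrillatory oscillation projected like atrial activity, and randomise
the RR series.  Mild age trends (T-wave amplitude, heart rate, PR interval)
give the signals an age-correlated nuisance component, which is what makes
age-confounded cohort sampling consequential downstream.

Dates are integer days since an arbitrary epoch; ages are whole years with a
365-day year.  A single integer seed fully determines the registry and every
signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

LEADS = ("I", "II", "III", "aVR", "aVL", "aVF",
         "V1", "V2", "V3", "V4", "V5", "V6")
WAVES = ("P", "Q", "R", "S", "T")

#: Per-wave projection weights onto the 12 leads (rows: leads, cols: P,Q,R,S,T).
#: Signs and relative sizes follow textbook lead morphology: dominant R in the
#: lateral leads, deep S and inverted T in V1, everything inverted in aVR.
LEAD_WAVE_WEIGHTS = np.array([
    #  P      Q      R      S      T
    [0.55,  0.50,  0.70,  0.40,  0.55],   # I
    [1.00,  0.80,  1.00,  0.80,  1.00],   # II
    [0.45,  0.40,  0.45,  0.50,  0.45],   # III
    [-0.75, -0.60, -0.85, -0.70, -0.75],  # aVR
    [0.25,  0.30,  0.30,  0.20,  0.20],   # aVL
    [0.70,  0.60,  0.70,  0.60,  0.70],   # aVF
    [0.65,  0.20,  0.35,  1.40, -0.30],   # V1
    [0.85,  0.30,  0.60,  1.20,  0.90],   # V2
    [0.85,  0.40,  0.85,  0.90,  0.95],   # V3
    [0.65,  0.70,  1.10,  0.60,  0.85],   # V4
    [0.60,  0.90,  1.05,  0.40,  0.75],   # V5
    [0.55,  0.80,  0.90,  0.30,  0.65],   # V6
])

#: Source-signal wave parameters: amplitude (mV), Gaussian sigma (s), centre
#: offset relative to the R peak (s).
WAVE_AMPLITUDES = {"P": 0.15, "Q": -0.10, "R": 1.00, "S": -0.25, "T": 0.35}
WAVE_WIDTHS = {"P": 0.022, "Q": 0.009, "R": 0.011, "S": 0.010, "T": 0.045}
#: With P onset at centre - 2.5 sigma (55 ms) and QRS onset at R - 45 ms, the
#: P centre offset of -150 ms yields the textbook PR interval of 160 ms.
WAVE_OFFSETS = {"P": -0.150, "Q": -0.030, "R": 0.0, "S": 0.030, "T": 0.300}

# fiducial conventions derived from the bump parameters
_P_HALF_DUR = 2.5 * WAVE_WIDTHS["P"]      # P onset/offset at +-2.5 sigma
_QRS_HALF_DUR = 0.045                     # QRS onset/offset at R -+ 45 ms


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class DiscreteFeatures:
    """Per-record discrete waveform features (the machine-extracted variables)."""

    age_years: float | None
    sex: str | None
    p_wave_duration_ms: float | None
    pr_interval_ms: float | None
    mean_rr_ms: float | None
    pq_segment_level_uv: float | None
    n_qrs: int | None
    avg_p_per_qrs: float | None
    av_ratio: float | None
    has_extrasystoles: bool | None
    n_qrs_rhythm: int | None = None
    missing_mask: dict[str, bool] = field(default_factory=dict)

    FIELDS = ("age_years", "sex", "p_wave_duration_ms", "pr_interval_ms",
              "mean_rr_ms", "pq_segment_level_uv", "n_qrs", "avg_p_per_qrs",
              "av_ratio", "has_extrasystoles", "n_qrs_rhythm")

    def __post_init__(self):
        for name in self.FIELDS:
            self.missing_mask.setdefault(name, getattr(self, name) is None)

    def is_missing(self, name: str) -> bool:
        # a field set to a value after construction is present regardless of
        # the recorded mask; a None value is always missing
        return getattr(self, name, None) is None

    def as_row(self) -> dict:
        row = {name: getattr(self, name) for name in self.FIELDS}
        row.update({f"missing_{name}": self.is_missing(name)
                    for name in self.FIELDS})
        return row


@dataclass
class ECGRecord:
    """One 12-lead, 10 s recording with metadata and generator ground truth."""

    ecg_id: str
    patient_id: str
    acquisition_day: int
    sampling_rate: int = 500
    duration_s: float = 10.0
    signals: np.ndarray | None = None          # (12, fs*duration) in mV
    rhythm_interpretation: str = "sinus_rhythm"
    discrete: DiscreteFeatures | None = None
    fiducials: list[dict[str, int]] | None = None
    class_effect: str = "none"                  # {"none", "pre_af"}
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration_s))


@dataclass
class Patient:
    patient_id: str
    sex: str                      # {"M", "F"}
    birth_day: int | None         # None models a missing-age registry entry
    group: str                    # {"AF", "SR"}
    index_day: int | None = None
    ecg_ids: list[str] = field(default_factory=list)

    def age_on(self, day: int) -> int | None:
        if self.birth_day is None:
            return None
        return (day - self.birth_day) // 365


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``delta_p`` is the planted class effect: P-wave amplitude multiplier for
    pre-AF sinus ECGs (1 = null, identical classes given age).  ``pq_shift_uv``
    shifts the PQ-segment level of the same records.  ``class_effect_leads``
    restricts both effects to named leads (None = all leads).
    """

    n_af_patients: int = 50
    n_sr_patients: int = 150
    # demographics (normal age model per group, paper-like defaults)
    af_age_mean: float = 80.0
    af_age_sd: float = 8.0
    sr_age_mean: float = 64.0
    sr_age_sd: float = 12.0
    female_fraction: float = 0.5
    # rhythm / beat model
    hr_range_bpm: tuple[float, float] = (55.0, 95.0)
    rr_jitter: float = 0.02
    first_r_offset_s: float = 0.3
    # per-ECG physiologic amplitude variability (lognormal sigmas): a global
    # record-level gain and independent per-wave jitters
    amp_scale_sd: float = 0.10
    wave_amp_jitter: float = 0.08
    # class effect: P amplitude multiplier delta_p, PQ level shift and P-wave
    # widening (interatrial-block-like prolongation), the latter two scaled by
    # (1 - delta_p) so delta_p = 1 is an exact null
    delta_p: float = 0.5
    pq_shift_uv: float = -20.0
    p_pre_af_widening: float = 1.4
    p_pre_af_morphology: str = "notched"   # {"notched", "widened"}
    class_effect_leads: tuple[str, ...] | None = None
    # age-correlated nuisance trends (centred at 60 years)
    t_amp_age_slope: float = 0.008     # relative T-amplitude loss per year
    hr_age_slope_bpm: float = 0.25     # mean heart-rate drift per year
    pr_age_slope_ms: float = 0.3       # PR-interval lengthening per year
    # noise
    noise_white_mv: float = 0.02
    baseline_wander_mv: float = 0.05
    baseline_wander_hz: float = 0.25
    # AF-rhythm parameters
    af_rr_cv: float = 0.2
    af_rr_cv_min: float = 0.08
    f_wave_amp_mv: float = 0.08
    f_wave_hz: float = 6.0
    # registry structure
    span_days: int = 3285              # ~9-year acquisition window
    missing_feature_rate: float = 0.03
    missing_age_rate: float = 0.02
    single_ecg_rate: float = 0.02
    mislabelled_af_rate: float = 0.05  # "AF" index ECGs that are really sinus
    post_index_sinus_rate: float = 0.4
    sampling_rate: int = 500
    duration_s: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_af_patients < 0 or self.n_sr_patients < 0:
            raise ConfigurationError("patient counts must be >= 0")
        for name in ("af_age_sd", "sr_age_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not 0 <= self.delta_p <= 1:
            raise ConfigurationError("delta_p must lie in [0, 1]")
        if self.hr_range_bpm[0] > self.hr_range_bpm[1] or self.hr_range_bpm[0] <= 0:
            raise ConfigurationError("invalid heart-rate range")
        n = self.sampling_rate * self.duration_s
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration * rate must be a positive integer")
        if self.class_effect_leads is not None:
            unknown = set(self.class_effect_leads) - set(LEADS)
            if unknown:
                raise ConfigurationError(f"unknown leads: {sorted(unknown)}")

    def effect_lead_indices(self) -> np.ndarray:
        if self.class_effect_leads is None:
            return np.arange(len(LEADS))
        return np.array([LEADS.index(l) for l in self.class_effect_leads])

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def planted_effect_config(delta_p: float = 0.4, **kw) -> SimulationConfig:
    """Conditions for the planted-effect benchmark.

    Identical age models in the two groups and no age trends in the signal,
    so discrimination can only come from the P-wave/PQ effect: the two groups
    acquire ECGs in different windows relative to their index dates, and any
    age-linked waveform drift would otherwise leak a class signal even at
    ``delta_p = 1``.
    """
    base = dict(af_age_mean=70.0, af_age_sd=10.0, sr_age_mean=70.0,
                sr_age_sd=10.0, delta_p=delta_p,
                t_amp_age_slope=0.0, hr_age_slope_bpm=0.0, pr_age_slope_ms=0.0)
    base.update(kw)
    return SimulationConfig(**base)


@dataclass
class Registry:
    patients: dict[str, Patient]
    ecgs: dict[str, ECGRecord]
    config: SimulationConfig
    log: list[dict] = field(default_factory=list)

    def patient_of(self, ecg_id: str) -> Patient:
        return self.patients[self.ecgs[ecg_id].patient_id]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _beat_times(rng: np.random.Generator, config: SimulationConfig,
                rhythm: str, hr_bpm: float) -> np.ndarray:
    mean_rr = 60.0 / hr_bpm
    horizon = config.duration_s + 1.0
    n_max = int(np.ceil(horizon / max(mean_rr * 0.4, 0.25))) + 2
    if rhythm == "af":
        rr = mean_rr * (1.0 + config.af_rr_cv * rng.standard_normal(n_max))
    else:
        rr = mean_rr * (1.0 + config.rr_jitter * rng.standard_normal(n_max))
    rr = np.clip(rr, 0.3, 2.5)
    times = config.first_r_offset_s + np.concatenate([[0.0], np.cumsum(rr)])
    return times[times < horizon]


def synthesize_ecg(patient: Patient, day: int, rhythm: str, class_effect: str,
                   config: SimulationConfig, seed: int,
                   ecg_id: str = "E0") -> ECGRecord:
    """Render one 12-lead record from the Gaussian-bump beat model.

    ``rhythm`` is ``"sinus"`` or ``"af"``; ``class_effect`` is ``"none"`` or
    ``"pre_af"`` (ignored for AF rhythm, which has no P wave to attenuate).
    """
    config.validate()
    if rhythm not in ("sinus", "af"):
        raise ConfigurationError(f"unknown rhythm {rhythm!r}")
    if class_effect not in ("none", "pre_af"):
        raise ConfigurationError(f"unknown class effect {class_effect!r}")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n = int(round(fs * config.duration_s))
    t = np.arange(n) / fs
    age = patient.age_on(day)
    age_c = 0.0 if age is None else age - 60.0

    hr = rng.uniform(*config.hr_range_bpm) + config.hr_age_slope_bpm * age_c
    hr = float(np.clip(hr, 40.0, 140.0))
    t_amp_factor = float(np.clip(1.0 - config.t_amp_age_slope * age_c, 0.4, 1.3))
    pr_shift_s = config.pr_age_slope_ms * age_c / 1000.0
    # record-level amplitude variability (electrode placement, habitus, gain)
    global_gain = float(np.exp(rng.normal(0.0, config.amp_scale_sd)))
    wave_gain = {w: float(np.exp(rng.normal(0.0, config.wave_amp_jitter)))
                 for w in WAVES}

    beat_r = _beat_times(rng, config, rhythm, hr)
    signals = np.zeros((12, n))
    effect_idx = config.effect_lead_indices()
    fiducials: list[dict[str, int]] = []

    pre_af = rhythm == "sinus" and class_effect == "pre_af"
    # P prolongation (interatrial-block-like), scaled with the effect size;
    # the "notched" morphology renders it as two part-fused humps (late
    # left-atrial activation), the "widened" one as a single broader Gaussian
    p_width_factor = (1.0 + (config.p_pre_af_widening - 1.0)
                      * (1.0 - config.delta_p)) if pre_af else 1.0
    notched = pre_af and config.p_pre_af_morphology == "notched"
    if notched:
        p_width = WAVE_WIDTHS["P"]
        hump_sep = 2 * 2.5 * p_width * (p_width_factor - 1.0)
        p_half_dur = 2.5 * p_width + hump_sep / 2.0
    else:
        p_width = WAVE_WIDTHS["P"] * p_width_factor
        hump_sep = 0.0
        p_half_dur = 2.5 * p_width

    for r_time in beat_r:
        p_center = r_time + WAVE_OFFSETS["P"] - pr_shift_s
        for wi, wave in enumerate(WAVES):
            if wave == "P":
                if rhythm == "af":
                    continue
                amp = WAVE_AMPLITUDES["P"] * global_gain * wave_gain["P"]
                base_w = LEAD_WAVE_WEIGHTS[:, wi]
                if pre_af:
                    # effect leads carry the attenuated, prolonged P; the
                    # rest keep the normal morphology
                    w_eff = np.zeros(12)
                    w_eff[effect_idx] = base_w[effect_idx] * config.delta_p
                    w_rest = base_w.copy()
                    w_rest[effect_idx] = 0.0
                    normal = amp * np.exp(
                        -0.5 * ((t - p_center) / WAVE_WIDTHS["P"]) ** 2)
                    if notched:
                        half = hump_sep / 2.0
                        shape = (np.exp(-0.5 * ((t - p_center + half)
                                               / p_width) ** 2)
                                 + np.exp(-0.5 * ((t - p_center - half)
                                                  / p_width) ** 2))
                        # peak-normalised so the morphology fuses smoothly
                        # into a single normal P as the effect vanishes; a
                        # P centred outside the record has zero support
                        peak = shape.max()
                        affected = amp * shape / peak if peak > 0 else shape
                    else:
                        affected = amp * np.exp(
                            -0.5 * ((t - p_center) / p_width) ** 2)
                    signals += w_rest[:, None] * normal[None, :]
                    signals += w_eff[:, None] * affected[None, :]
                else:
                    bump = amp * np.exp(
                        -0.5 * ((t - p_center) / WAVE_WIDTHS["P"]) ** 2)
                    signals += base_w[:, None] * bump[None, :]
                continue
            amp = WAVE_AMPLITUDES[wave] * global_gain * wave_gain[wave]
            width = WAVE_WIDTHS[wave]
            center = r_time + WAVE_OFFSETS[wave]
            if wave == "T":
                amp = amp * t_amp_factor
            bump = amp * np.exp(-0.5 * ((t - center) / width) ** 2)
            signals += LEAD_WAVE_WEIGHTS[:, wi][:, None] * bump[None, :]

        # PQ-segment level shift for the planted pre-AF effect; scaled by
        # (1 - delta_p) so delta_p = 1 leaves the classes exchangeable
        pq_shift = config.pq_shift_uv * (1.0 - config.delta_p)
        if pre_af and pq_shift:
            pq_lo = p_center + p_half_dur
            pq_hi = r_time - _QRS_HALF_DUR
            mask = (t >= pq_lo) & (t < pq_hi)
            if mask.any():
                signals[np.ix_(effect_idx, np.where(mask)[0])] += pq_shift / 1000.0

        # ground-truth fiducials for beats fully inside the record
        marks = {
            "qrs_onset": r_time - _QRS_HALF_DUR,
            "r_peak": r_time,
            "qrs_offset": r_time + _QRS_HALF_DUR,
            "t_peak": r_time + WAVE_OFFSETS["T"],
        }
        if rhythm == "sinus":
            marks.update({
                "p_onset": p_center - p_half_dur,
                "p_peak": p_center,
                "p_offset": p_center + p_half_dur,
            })
        idx = {k: int(round(v * fs)) for k, v in marks.items()}
        if all(0 <= v < n for v in idx.values()):
            fiducials.append(idx)

    if rhythm == "af" and config.f_wave_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + 0.3 * np.sin(2 * np.pi * 0.5 * t + rng.uniform(0, 2 * np.pi))
        fwave = config.f_wave_amp_mv * envelope * np.sin(
            2 * np.pi * config.f_wave_hz * t + phase)
        signals += LEAD_WAVE_WEIGHTS[:, 0][:, None] * fwave[None, :]

    if config.baseline_wander_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        wander = np.sin(2 * np.pi * config.baseline_wander_hz * t + phase)
        per_lead = config.baseline_wander_mv * rng.uniform(0.5, 1.5, 12)
        signals += per_lead[:, None] * wander[None, :]
    if config.noise_white_mv > 0:
        signals += rng.normal(0.0, config.noise_white_mv, signals.shape)

    record = ECGRecord(
        ecg_id=ecg_id, patient_id=patient.patient_id, acquisition_day=day,
        sampling_rate=fs, duration_s=config.duration_s,
        signals=signals.astype(np.float64),
        rhythm_interpretation="atrial_fibrillation" if rhythm == "af" else "sinus_rhythm",
        fiducials=sorted(fiducials, key=lambda d: d["r_peak"]),
        class_effect=class_effect if rhythm == "sinus" else "none",
        seed=seed,
    )
    return record


# ---------------------------------------------------------------------------
# registry generation
# ---------------------------------------------------------------------------

def _machine_features(rng: np.random.Generator, config: SimulationConfig,
                      age: int | None, sex: str, rhythm: str,
                      class_effect: str, hr_hint: float) -> DiscreteFeatures:
    """Analytic stand-in for the recorder's discrete feature extraction."""
    age_c = 0.0 if age is None else age - 60.0
    if rhythm == "af":
        mean_rr = 60000.0 / hr_hint
        feats = DiscreteFeatures(
            age_years=age, sex=sex, p_wave_duration_ms=None, pr_interval_ms=None,
            mean_rr_ms=mean_rr, pq_segment_level_uv=None,
            n_qrs=int(config.duration_s * hr_hint / 60.0),
            avg_p_per_qrs=0.0, av_ratio=0.0, has_extrasystoles=False)
        feats.n_qrs_rhythm = feats.n_qrs
        return feats
    pre_af = class_effect == "pre_af"
    p_factor = (1.0 + (config.p_pre_af_widening - 1.0)
                * (1.0 - config.delta_p)) if pre_af else 1.0
    p_dur = 1000.0 * 2 * _P_HALF_DUR * p_factor + rng.normal(0, 3.0)
    # P onset moves earlier as the P widens around its fixed centre
    pr = (160.0 + 1000.0 * _P_HALF_DUR * (p_factor - 1.0)
          + config.pr_age_slope_ms * age_c) + rng.normal(0, 2.0)
    mean_rr = 60000.0 / hr_hint + rng.normal(0, 5.0)
    pq = (config.pq_shift_uv * (1.0 - config.delta_p) if pre_af else 0.0
          ) + rng.normal(0, 5.0)
    n_qrs = max(int(config.duration_s * hr_hint / 60.0), 1)
    feats = DiscreteFeatures(
        age_years=age, sex=sex,
        p_wave_duration_ms=(None if pre_af and config.delta_p == 0 else p_dur),
        pr_interval_ms=(None if pre_af and config.delta_p == 0 else pr),
        mean_rr_ms=mean_rr, pq_segment_level_uv=pq, n_qrs=n_qrs,
        avg_p_per_qrs=0.0 if (pre_af and config.delta_p == 0) else 1.0,
        av_ratio=0.0 if (pre_af and config.delta_p == 0) else 1.0,
        has_extrasystoles=bool(rng.random() < 0.01))
    feats.n_qrs_rhythm = n_qrs
    # registry-level missingness, to exercise the MLR discard rule
    for name in ("p_wave_duration_ms", "pr_interval_ms", "pq_segment_level_uv",
                 "mean_rr_ms"):
        if rng.random() < config.missing_feature_rate:
            setattr(feats, name, None)
            feats.missing_mask[name] = True
    return feats


def generate_registry(config: SimulationConfig) -> Registry:
    """Generate the patient registry and full ECG acquisition schedule.

    Signals are not rendered here; every scheduled record stores a derived seed
    so :func:`realize_signals` can synthesize it reproducibly on demand.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    patients: dict[str, Patient] = {}
    ecgs: dict[str, ECGRecord] = {}
    log: list[dict] = []
    counter = 0

    def new_record(patient: Patient, day: int, rhythm: str, effect: str,
                   hr_hint: float, mislabelled: bool = False) -> ECGRecord:
        nonlocal counter
        counter += 1
        ecg_id = f"E{counter:06d}"
        seed = int(rng.integers(1, 2**31 - 1))
        age = patient.age_on(day)
        # a mislabelled "AF" record is a sinus signal carrying an AF label
        true_rhythm = "sinus" if mislabelled else rhythm
        feats = _machine_features(rng, config, age, patient.sex,
                                  true_rhythm, effect, hr_hint)
        rec = ECGRecord(
            ecg_id=ecg_id, patient_id=patient.patient_id, acquisition_day=int(day),
            sampling_rate=config.sampling_rate, duration_s=config.duration_s,
            rhythm_interpretation=("atrial_fibrillation" if rhythm == "af"
                                   else "sinus_rhythm"),
            discrete=feats, class_effect=effect if true_rhythm == "sinus" else "none",
            seed=seed)
        if mislabelled:
            # signal will be rendered as sinus despite the AF interpretation
            rec.class_effect = effect
            rec.rhythm_interpretation = "atrial_fibrillation"
            rec.seed = -seed  # marker consumed by realize_signals via sign
        ecgs[ecg_id] = rec
        patient.ecg_ids.append(ecg_id)
        return rec

    def base_hr(age: int | None) -> float:
        age_c = 0.0 if age is None else age - 60.0
        hr = rng.uniform(*config.hr_range_bpm) + config.hr_age_slope_bpm * age_c
        return float(np.clip(hr, 40.0, 140.0))

    # ---- AF group ---------------------------------------------------------
    for i in range(config.n_af_patients):
        pid = f"A{i + 1:05d}"
        sex = "F" if rng.random() < config.female_fraction else "M"
        index_day = int(rng.integers(1500, config.span_days - 30))
        age_at_index = float(np.clip(rng.normal(config.af_age_mean,
                                                config.af_age_sd), 20, 100))
        birth_day = index_day - int(age_at_index * 365) - int(rng.integers(0, 365))
        if rng.random() < config.missing_age_rate:
            birth_day = None
        patient = Patient(pid, sex, birth_day, "AF", index_day=None)
        patients[pid] = patient
        hr = base_hr(patient.age_on(index_day))

        mislabelled = rng.random() < config.mislabelled_af_rate
        new_record(patient, index_day, "af", "none", hr, mislabelled=mislabelled)
        if rng.random() < config.single_ecg_rate:
            continue  # single-ECG fixture, removed later by the cohort stage
        # evaluation-window sinus ECGs: 2 months to 1 week before the index
        for _ in range(1 + rng.poisson(0.8)):
            day = int(rng.integers(index_day - 60, index_day - 6))
            new_record(patient, day, "sinus", "pre_af", hr)
        # deeper sinus history
        for _ in range(rng.poisson(2.0)):
            day = int(rng.integers(max(index_day - 2000, 0), index_day - 60))
            new_record(patient, day, "sinus", "pre_af", hr)
        # occasional post-index sinus ECGs (second-phase fallback material)
        if rng.random() < config.post_index_sinus_rate:
            day = int(rng.integers(index_day + 30,
                                   max(index_day + 400, index_day + 31)))
            new_record(patient, day, "sinus", "pre_af", hr)

    # ---- SR group ---------------------------------------------------------
    for i in range(config.n_sr_patients):
        pid = f"S{i + 1:05d}"
        sex = "F" if rng.random() < config.female_fraction else "M"
        index_day = int(rng.integers(1500, config.span_days))
        age_at_index = float(np.clip(rng.normal(config.sr_age_mean,
                                                config.sr_age_sd), 18, 100))
        birth_day = index_day - int(age_at_index * 365) - int(rng.integers(0, 365))
        if rng.random() < config.missing_age_rate:
            birth_day = None
        patient = Patient(pid, sex, birth_day, "SR", index_day=None)
        patients[pid] = patient
        hr = base_hr(patient.age_on(index_day))

        if rng.random() < config.single_ecg_rate:
            new_record(patient, index_day, "sinus", "none", hr)
            continue
        n_hist = 1 + rng.poisson(2.0)
        days = sorted(int(d) for d in rng.integers(0, index_day - 30, n_hist))
        for day in days:
            new_record(patient, day, "sinus", "none", hr)
        new_record(patient, index_day, "sinus", "none", hr)  # last = index

    log.append({"event": "registry_generated",
                "n_af": config.n_af_patients, "n_sr": config.n_sr_patients,
                "n_ecgs": len(ecgs)})
    return Registry(patients=patients, ecgs=ecgs, config=config, log=log)


def realize_signals(record: ECGRecord, registry: Registry) -> ECGRecord:
    """Synthesize (in place) the signal of a registry record from its stored seed.

    A negative stored seed marks a mislabelled index record: the interpretation
    says AF but the rendered signal is sinus (what the rhythm double-confirmation
    stage exists to catch).
    """
    if record.signals is not None:
        return record
    patient = registry.patients[record.patient_id]
    mislabelled = record.seed < 0
    seed = abs(record.seed)
    rhythm = ("sinus" if mislabelled else
              ("af" if record.rhythm_interpretation == "atrial_fibrillation"
               else "sinus"))
    full = synthesize_ecg(patient, record.acquisition_day, rhythm,
                          record.class_effect, registry.config, seed,
                          ecg_id=record.ecg_id)
    record.signals = full.signals
    record.fiducials = full.fiducials
    return record


# ---------------------------------------------------------------------------
# discrete feature detection
# ---------------------------------------------------------------------------

_RHYTHM_LEAD = 1  # lead II drives peak detection

# conventional estimator offsets for the detection path (ms)
_P_ONSET_BACKOFF_MS = 55.0
_QRS_ONSET_BACKOFF_MS = 45.0


def compute_discrete_features(record: ECGRecord,
                              use_fiducials: bool = False) -> DiscreteFeatures:
    """Extract discrete waveform features from a (preferably clean) signal.

    The default path runs threshold-based R-peak detection plus a windowed P
    search on lead II.  With ``use_fiducials=True`` the generator's ground-truth
    fiducials are read instead (test mode).  Records with fewer than two
    detected R peaks get all interval features flagged missing.
    """
    if record.signals is None:
        raise ValueError("record has no signals; call realize_signals first")
    fs = record.sampling_rate
    sig = record.signals[_RHYTHM_LEAD]
    n = sig.size
    age = record.discrete.age_years if record.discrete is not None else None
    sex = record.discrete.sex if record.discrete is not None else None

    if use_fiducials and record.fiducials:
        r_idx = np.array([b["r_peak"] for b in record.fiducials])
        p_idx = np.array([b["p_peak"] for b in record.fiducials if "p_peak" in b])
    else:
        height = 0.5 * np.max(sig) if np.max(sig) > 0 else None
        r_idx, _ = find_peaks(sig, height=height, distance=int(0.3 * fs))
        p_idx = []
        for r in r_idx:
            lo = max(r - int(0.25 * fs), 0)
            hi = r - int(0.08 * fs)
            if hi <= lo:
                continue
            window = sig[lo:hi]
            k = int(np.argmax(window))
            baseline = np.median(window)
            if window[k] - baseline > 0.06:
                p_idx.append(lo + k)
        p_idx = np.array(p_idx, dtype=int)

    n_qrs = int(r_idx.size)
    missing: dict[str, bool] = {}
    if n_qrs < 2:
        feats = DiscreteFeatures(
            age_years=age, sex=sex, p_wave_duration_ms=None, pr_interval_ms=None,
            mean_rr_ms=None, pq_segment_level_uv=None, n_qrs=n_qrs,
            avg_p_per_qrs=None, av_ratio=None, has_extrasystoles=None)
        feats.n_qrs_rhythm = n_qrs
        return feats

    rr = np.diff(r_idx) / fs * 1000.0
    mean_rr = float(np.mean(rr))
    has_extra = bool(np.min(rr) < 0.75 * np.median(rr))
    avg_p_per_qrs = float(len(p_idx) / n_qrs)
    av_ratio = avg_p_per_qrs  # atrial vs ventricular rate over the same window

    pr_ms = None
    p_dur_ms = None
    pq_uv = None
    if len(p_idx) > 0:
        # pair each P with the following R
        pr_vals, pq_vals, dur_vals = [], [], []
        for p in p_idx:
            later = r_idx[r_idx > p]
            if later.size == 0:
                continue
            r = later[0]
            pr_vals.append((r - p) / fs * 1000.0
                           + _P_ONSET_BACKOFF_MS - _QRS_ONSET_BACKOFF_MS)
            lo = p + int(_P_HALF_DUR * fs)
            hi = r - int(_QRS_ONSET_BACKOFF_MS / 1000.0 * fs)
            if hi > lo:
                pq_vals.append(np.mean(sig[lo:hi]) * 1000.0)
            # width where the bump exceeds 10% of its prominence
            amp = sig[p] - np.median(sig[max(p - int(0.2 * fs), 0):p + 1])
            if amp > 0:
                thresh = sig[p] - 0.9 * amp
                left = p
                while left > 0 and sig[left] > thresh:
                    left -= 1
                right = p
                while right < n - 1 and sig[right] > thresh:
                    right += 1
                dur_vals.append((right - left) / fs * 1000.0)
        if pr_vals:
            pr_ms = float(np.mean(pr_vals))
        if pq_vals:
            pq_uv = float(np.mean(pq_vals))
        if dur_vals:
            p_dur_ms = float(np.mean(dur_vals))
    for name, val in (("pr_interval_ms", pr_ms), ("p_wave_duration_ms", p_dur_ms),
                      ("pq_segment_level_uv", pq_uv)):
        missing[name] = val is None

    feats = DiscreteFeatures(
        age_years=age, sex=sex, p_wave_duration_ms=p_dur_ms, pr_interval_ms=pr_ms,
        mean_rr_ms=mean_rr, pq_segment_level_uv=pq_uv, n_qrs=n_qrs,
        avg_p_per_qrs=avg_p_per_qrs, av_ratio=av_ratio,
        has_extrasystoles=has_extra, missing_mask=missing)
    feats.n_qrs_rhythm = n_qrs
    return feats


# ---------------------------------------------------------------------------
# exclusion-rule fixtures
# ---------------------------------------------------------------------------

def make_violation_fixtures(config: SimulationConfig | None = None
                            ) -> list[tuple[ECGRecord, str]]:
    """One record per exclusion rule plus one clean record.

    Each fixture is a rendered sinus record whose attached discrete features
    violate exactly the named rule (the signal itself is ordinary; the features
    are what the exclusion stage consumes).
    """
    config = (config or SimulationConfig()).replace(
        noise_white_mv=0.0, baseline_wander_mv=0.0, rr_jitter=0.0,
        hr_range_bpm=(70.0, 70.0))
    patient = Patient("FIX01", "M", birth_day=0, group="SR")

    def base(ecg_id: str, seed: int) -> ECGRecord:
        rec = synthesize_ecg(patient, 40 * 365, "sinus", "none", config,
                             seed=seed, ecg_id=ecg_id)
        rec.discrete = DiscreteFeatures(
            age_years=40, sex="M", p_wave_duration_ms=110.0,
            pr_interval_ms=160.0, mean_rr_ms=857.0, pq_segment_level_uv=0.0,
            n_qrs=11, avg_p_per_qrs=1.0, av_ratio=1.0, has_extrasystoles=False)
        rec.discrete.n_qrs_rhythm = 11
        return rec

    fixtures = []
    rec = base("FIX_AGE", 1)
    rec.discrete.age_years = 17
    fixtures.append((rec, "age_lt_18"))

    rec = base("FIX_EXTRA", 2)
    rec.discrete.has_extrasystoles = True
    fixtures.append((rec, "extrasystoles"))

    rec = base("FIX_AVHI", 3)
    rec.discrete.av_ratio = 3.0
    fixtures.append((rec, "av_ratio_high"))

    rec = base("FIX_AVLO", 4)
    rec.discrete.av_ratio = 0.4
    fixtures.append((rec, "av_ratio_low"))

    # > 1 so the literal QRS-count rule (n_rhythm > avg_p * n_qrs) stays quiet
    rec = base("FIX_PQRS", 5)
    rec.discrete.avg_p_per_qrs = 1.2
    fixtures.append((rec, "p_per_qrs_ne_1"))

    rec = base("FIX_QRSR", 6)
    rec.discrete.n_qrs_rhythm = 20
    fixtures.append((rec, "qrs_rhythm_count"))

    fixtures.append((base("FIX_CLEAN", 7), "none"))
    return fixtures


# ---------------------------------------------------------------------------
# registry summaries
# ---------------------------------------------------------------------------

def registry_frames(registry: Registry):
    """Registry as (patients, ecgs) pandas DataFrames with documented columns."""
    import pandas as pd

    prows = [{
        "patient_id": p.patient_id, "sex": p.sex, "birth_day": p.birth_day,
        "group": p.group, "index_day": p.index_day, "n_ecgs": len(p.ecg_ids),
    } for p in registry.patients.values()]
    erows = []
    for rec in registry.ecgs.values():
        row = {"ecg_id": rec.ecg_id, "patient_id": rec.patient_id,
               "acquisition_day": rec.acquisition_day,
               "rhythm_interpretation": rec.rhythm_interpretation,
               "class_effect": rec.class_effect}
        if rec.discrete is not None:
            row.update(rec.discrete.as_row())
        erows.append(row)
    return pd.DataFrame(prows), pd.DataFrame(erows)
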