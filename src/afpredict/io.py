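"""Cohort container I/O: HDF5 layout, CSV tables, WFDB export, YAML configs.

Layout of a cohort file: ``/patients`` and ``/ecgs`` tables (HDF5 datasets of
fixed-width fields; a sentinel encodes a missing day), per-record signal
arrays under
``/signals/<ecg_id>`` (12 x n float32, millivolts) when rendered, and the
simulation configuration as a YAML string attribute, so a cohort file is
self-describing and fully reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synthetic_data import (DiscreteFeatures, ECGRecord, Patient, Registry,
                             SimulationConfig)

_STR = h5py.string_dtype(encoding="utf-8")

# birth days are negative for anyone born before the study epoch, so missing
# dates need a sentinel far outside any plausible calendar value
_MISSING_DAY = -(10 ** 9)


def config_to_yaml(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return yaml.safe_dump(d)


def config_from_yaml(text: str) -> SimulationConfig:
    d = yaml.safe_load(text) or {}
    fields = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise KeyError(f"unknown simulation config key {k!r}")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return SimulationConfig(**kwargs)


def load_config_file(path: str | Path) -> SimulationConfig:
    return config_from_yaml(Path(path).read_text())


def save_cohort(registry: Registry, path: str | Path,
                include_signals: bool = False) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = config_to_yaml(registry.config)
        f.attrs["log_json"] = json.dumps(registry.log)
        pats = sorted(registry.patients.values(), key=lambda p: p.patient_id)
        f.create_dataset("patients/patient_id",
                         data=[p.patient_id for p in pats], dtype=_STR)
        f.create_dataset("patients/sex", data=[p.sex for p in pats], dtype=_STR)
        f.create_dataset("patients/group", data=[p.group for p in pats],
                         dtype=_STR)
        f.create_dataset("patients/birth_day",
                         data=[_MISSING_DAY if p.birth_day is None
                               else p.birth_day for p in pats])
        f.create_dataset("patients/index_day",
                         data=[_MISSING_DAY if p.index_day is None
                               else p.index_day for p in pats])
        recs = sorted(registry.ecgs.values(), key=lambda r: r.ecg_id)
        g = f.create_group("ecgs")
        g.create_dataset("ecg_id", data=[r.ecg_id for r in recs], dtype=_STR)
        g.create_dataset("patient_id", data=[r.patient_id for r in recs],
                         dtype=_STR)
        g.create_dataset("acquisition_day",
                         data=[r.acquisition_day for r in recs])
        g.create_dataset("rhythm", data=[r.rhythm_interpretation for r in recs],
                         dtype=_STR)
        g.create_dataset("class_effect", data=[r.class_effect for r in recs],
                         dtype=_STR)
        g.create_dataset("seed", data=[r.seed for r in recs])
        g.create_dataset("sampling_rate", data=[r.sampling_rate for r in recs])
        g.create_dataset("duration_s", data=[r.duration_s for r in recs])
        feat_json = [json.dumps(_features_to_jsonable(r.discrete))
                     for r in recs]
        g.create_dataset("discrete_json", data=feat_json, dtype=_STR)
        if include_signals:
            sg = f.create_group("signals")
            for r in recs:
                if r.signals is not None:
                    sg.create_dataset(r.ecg_id, data=r.signals.astype(np.float32))


def load_cohort(path: str | Path) -> Registry:
    with h5py.File(path, "r") as f:
        config = config_from_yaml(f.attrs["config_yaml"])
        log = json.loads(f.attrs.get("log_json", "[]"))
        patients = {}
        p = f["patients"]
        for i in range(len(p["patient_id"])):
            birth = int(p["birth_day"][i])
            index = int(p["index_day"][i])
            pat = Patient(
                patient_id=p["patient_id"][i].decode(),
                sex=p["sex"][i].decode(),
                birth_day=None if birth == _MISSING_DAY else birth,
                group=p["group"][i].decode(),
                index_day=None if index == _MISSING_DAY else index)
            patients[pat.patient_id] = pat
        ecgs = {}
        g = f["ecgs"]
        for i in range(len(g["ecg_id"])):
            rec = ECGRecord(
                ecg_id=g["ecg_id"][i].decode(),
                patient_id=g["patient_id"][i].decode(),
                acquisition_day=int(g["acquisition_day"][i]),
                sampling_rate=int(g["sampling_rate"][i]),
                duration_s=float(g["duration_s"][i]),
                rhythm_interpretation=g["rhythm"][i].decode(),
                class_effect=g["class_effect"][i].decode(),
                seed=int(g["seed"][i]),
                discrete=_features_from_jsonable(
                    json.loads(g["discrete_json"][i].decode())))
            if "signals" in f and rec.ecg_id in f["signals"]:
                rec.signals = np.asarray(f["signals"][rec.ecg_id], dtype=float)
            ecgs[rec.ecg_id] = rec
            patients[rec.patient_id].ecg_ids.append(rec.ecg_id)
        for pat in patients.values():
            pat.ecg_ids.sort(key=lambda e: ecgs[e].acquisition_day)
    return Registry(patients=patients, ecgs=ecgs, config=config, log=log)


def _features_to_jsonable(d: DiscreteFeatures | None) -> dict | None:
    if d is None:
        return None
    return d.as_row()


def _features_from_jsonable(row: dict | None) -> DiscreteFeatures | None:
    if row is None:
        return None
    kwargs = {name: row.get(name) for name in DiscreteFeatures.FIELDS}
    mask = {k[len("missing_"):]: bool(v)
            for k, v in row.items() if k.startswith("missing_")}
    return DiscreteFeatures(missing_mask=mask, **kwargs)


# ---------------------------------------------------------------------------
# WFDB-compatible export
# ---------------------------------------------------------------------------

_WFDB_GAIN = 200.0       # ADC units per millivolt
_LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
               "V1", "V2", "V3", "V4", "V5", "V6")


def export_wfdb(record: ECGRecord, directory: str | Path) -> Path:
    """Write ``<ecg_id>.hea`` / ``<ecg_id>.dat`` (format 16) for one record.

    Samples are quantised at 200 ADU/mV into interleaved little-endian 16-bit
    integers, the layout standard WFDB readers expect.
    """
    if record.signals is None:
        raise ValueError("record has no signals to export")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.ecg_id
    n_sig, n_samp = record.signals.shape
    adc = np.clip(np.round(record.signals * _WFDB_GAIN), -32768, 32767
                  ).astype("<i2")
    interleaved = adc.T.reshape(-1)
    (directory / f"{name}.dat").write_bytes(interleaved.tobytes())
    lines = [f"{name} {n_sig} {record.sampling_rate} {n_samp}"]
    for i in range(n_sig):
        checksum = int(np.sum(adc[i], dtype=np.int64) % 65536)
        if checksum >= 32768:
            checksum -= 65536
        lines.append(f"{name}.dat 16 {_WFDB_GAIN:g}/mV 16 0 "
                     f"{int(adc[i, 0])} {checksum} 0 {_LEAD_NAMES[i]}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


def read_wfdb_signals(header_path: str | Path) -> np.ndarray:
    """Read back a record written by :func:`export_wfdb` (verification aid)."""
    header_path = Path(header_path)
    lines = header_path.read_text().strip().splitlines()
    name, n_sig, _fs, n_samp = lines[0].split()[:4]
    n_sig, n_samp = int(n_sig), int(n_samp)
    gain = float(lines[1].split()[2].split("/")[0])
    raw = np.frombuffer((header_path.parent / f"{name}.dat").read_bytes(),
                        dtype="<i2")
    return raw.reshape(n_samp, n_sig).T / gain


def registry_to_csvs(registry: Registry, directory: str | Path) -> None:
    from .synthetic_data import registry_frames

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients, ecgs = registry_frames(registry)
    patients.to_csv(directory / "patients.csv", index=False)
    ecgs.to_csv(directory / "ecgs.csv", index=False)
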