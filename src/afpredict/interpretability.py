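"""Class-activation attribution over (time, lead) for the resnet model.

Because the resnet ends in global average pooling followed by one linear
layer, Grad-CAM reduces to plain CAM: the class-discriminative map is the
channel-weighted sum of the last residual block's (time, lead) feature maps,
with weights taken either from the final linear layer (CAM) or from the
pooled gradient of the target logit (Grad-CAM) — the two are proportional for
this architecture, which the test suite verifies numerically.

Conventions: ``target="af"`` uses the AF logit direction, ``"af_absence"``
its negation.  The signed raw map is kept for statistics (lead contributions
may legitimately be negative); the [0, 1] min-max normalised map is for
display and for segment attribution.  Maps are linearly upsampled along time
back to input resolution; leads are categorical and never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelData, ResNetClassifier
from .synthetic_data import ConfigurationError, LEADS


@dataclass
class CAMMap:
    ecg_id: str
    target: str                    # {"af", "af_absence"}
    raw_map: np.ndarray            # (time, lead), signed
    normalized_map: np.ndarray     # (time, lead) in [0, 1]
    upsampling_factor: float


def normalize_map(raw: np.ndarray) -> np.ndarray:
    lo, hi = float(raw.min()), float(raw.max())
    if hi > lo:
        return (raw - lo) / (hi - lo)
    return np.zeros_like(raw)


def _upsample_time(arr: np.ndarray, n_out: int,
                   shift_input_samples: float = 0.0) -> np.ndarray:
    """Linear interpolation along axis 0 from (t, leads) to (n_out, leads).

    ``shift_input_samples`` compensates the trunk's accumulated group delay
    (asymmetric 'same' padding of even kernels), in input-resolution samples,
    so map features line up with the waveform they were computed from.
    """
    t_in = arr.shape[0]
    if t_in == n_out and shift_input_samples == 0.0:
        return arr
    factor = n_out / t_in
    # map cell j is centred on input sample j*factor + factor/2 + shift
    centres = np.arange(t_in) * factor + factor / 2.0 + shift_input_samples
    x_out = np.arange(n_out)
    return np.stack([np.interp(x_out, centres, arr[:, j])
                     for j in range(arr.shape[1])], axis=1)


def grad_cam(model, data: ModelData, index: int, target: str = "af",
             mode: str = "cam", n_out: int = 5000,
             apply_relu: bool = False) -> CAMMap:
    """Attribution map for one record of ``data``.

    ``mode="cam"`` weights the feature maps by the final linear layer;
    ``mode="grad-cam"`` weights them by the pooled gradient of the target
    logit (identical up to a positive scalar for this GAP + linear head).
    ``apply_relu`` clips the raw map at zero before normalisation, for
    conventional Grad-CAM visuals.
    """
    if not isinstance(model, ResNetClassifier):
        raise ConfigurationError(
            "attribution requires the CAM-compatible resnet architecture "
            "(GAP followed by a single linear layer)")
    if target not in ("af", "af_absence"):
        raise ConfigurationError(f"unknown target {target!r}")
    maps = model.activation_maps(data, [index])[0]     # (C, leads, L)
    C, n_leads, L = maps.shape
    if mode == "cam":
        w = model.cam_weights.astype(float)
    elif mode == "grad-cam":
        # pooled gradient of the target logit w.r.t. the feature maps,
        # obtained by differentiating through the head
        from . import nn

        A = nn.Tensor(maps[None].astype(nn.DTYPE), requires_grad=True)
        pooled = nn.reduce_mean(A, axis=(2, 3))
        logit = model.head(pooled)
        logit.backward()
        w = A.grad[0].mean(axis=(1, 2)).astype(float)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if target == "af_absence":
        w = -w
    raw = np.tensordot(w, maps.astype(float), axes=(0, 0))  # (leads, L)
    raw = raw.T                                             # (time, lead)
    if apply_relu:
        raw = np.maximum(raw, 0.0)
    stride, delay = model.cam_alignment()
    raw_up = _upsample_time(raw, n_out,
                            shift_input_samples=delay * n_out / (L * stride))
    return CAMMap(ecg_id=data.ecg_ids[index], target=target, raw_map=raw_up,
                  normalized_map=normalize_map(raw_up),
                  upsampling_factor=n_out / L)


# ---------------------------------------------------------------------------
# lead contributions
# ---------------------------------------------------------------------------

def lead_contribution_summary(cam_maps: Sequence[CAMMap],
                              predictions: Sequence[int],
                              labels: Sequence[int],
                              strata: Sequence[str] | None = None
                              ) -> pd.DataFrame:
    """Mean signed per-lead contribution with 95% t-CIs, per stratum and target.

    Only correctly classified records enter the statistics: maps with
    ``target="af"`` are summarised over correct AF records, maps with
    ``target="af_absence"`` over correct SR records.  A record's lead
    contribution is the time average of its signed raw map in that lead.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if strata is None:
        strata = ["all"] * len(cam_maps)
    rows = []
    keys = sorted({(s, m.target) for s, m in zip(strata, cam_maps)})
    for stratum, target in keys:
        wanted_label = 1 if target == "af" else 0
        per_record = [m.raw_map.mean(axis=0)
                      for m, s, p, y in zip(cam_maps, strata, predictions, labels)
                      if s == stratum and m.target == target
                      and p == y and y == wanted_label]
        if not per_record:
            for lead in LEADS:
                rows.append({"stratum": stratum, "target": target, "lead": lead,
                             "mean": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "n": 0, "flag": "empty"})
            continue
        mat = np.stack(per_record)                     # (n, leads)
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        if n > 1:
            half = stats.t.ppf(0.975, n - 1) * mat.std(axis=0, ddof=1) / np.sqrt(n)
            flag = ""
        else:
            half = np.zeros(len(LEADS))
            flag = "degenerate_ci"
        for j, lead in enumerate(LEADS):
            rows.append({"stratum": stratum, "target": target, "lead": lead,
                         "mean": float(mean[j]),
                         "ci_low": float(mean[j] - half[j]),
                         "ci_high": float(mean[j] + half[j]),
                         "n": n, "flag": flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# segment attribution
# ---------------------------------------------------------------------------

SEGMENTS = ("pre_p_baseline", "p_wave", "qrs_first_half", "qrs_second_half",
            "t_wave", "other")

_PRE_P_SECONDS = 0.08
_T_HALF_SECONDS = 0.10


def segment_labels(fiducials: Sequence[dict], n_samples: int,
                   fs: float) -> np.ndarray:
    """Exhaustive, disjoint segment id per sample from ground-truth fiducials."""
    if not fiducials:
        raise ConfigurationError("segment attribution needs fiducials")
    lab = np.full(n_samples, SEGMENTS.index("other"), dtype=np.int8)

    def fill(lo: int, hi: int, name: str):
        lo, hi = max(lo, 0), min(hi, n_samples)
        if hi > lo:
            lab[lo:hi] = SEGMENTS.index(name)

    t_half = int(_T_HALF_SECONDS * fs)
    pre_p = int(_PRE_P_SECONDS * fs)
    for beat in fiducials:
        if "t_peak" in beat:
            fill(beat["t_peak"] - t_half, beat["t_peak"] + t_half, "t_wave")
    for beat in fiducials:
        if "p_onset" in beat:
            fill(beat["p_onset"] - pre_p, beat["p_onset"], "pre_p_baseline")
            fill(beat["p_onset"], beat["p_offset"], "p_wave")
        fill(beat["qrs_onset"], beat["r_peak"], "qrs_first_half")
        fill(beat["r_peak"], beat["qrs_offset"], "qrs_second_half")
    return lab


def segment_attribution(cam_map: CAMMap, fiducials: Sequence[dict],
                        fs: float = 500.0) -> dict[str, dict[str, float]]:
    """Importance mass fractions (and densities) over the beat segments.

    Masses come from the [0, 1] normalised map summed over leads; fractions
    sum to one over the exhaustive partition, and the density divides each
    mass by its segment length so segments of different durations compare
    fairly.
    """
    n_samples = cam_map.normalized_map.shape[0]
    lab = segment_labels(fiducials, n_samples, fs)
    weight = cam_map.normalized_map.sum(axis=1)          # over leads
    total = float(weight.sum())
    fractions, densities = {}, {}
    for k, name in enumerate(SEGMENTS):
        mask = lab == k
        mass = float(weight[mask].sum())
        length = int(mask.sum())
        fractions[name] = mass / total if total > 0 else 0.0
        densities[name] = (mass / length) if length > 0 else 0.0
    return {"fraction": fractions, "density": densities,
            "segment_samples": {name: int((lab == k).sum())
                                for k, name in enumerate(SEGMENTS)}}
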