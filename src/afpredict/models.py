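"""The six AF-score models and their training protocol.

Every model maps one sinus-rhythm 12-lead ECG (optionally with age and sex)
to an AF score in [0, 1], the estimated risk of a future AF episode:

1. ``resnet`` — three 1-D residual blocks convolving along time only (leads
   share weights and stay separate), global average pooling over the
   (time, lead) maps of the last block, and a single linear output.  This
   GAP + linear head is what makes class activation mapping applicable.
2. ``resnet_demo`` — same trunk; the pooled features are reduced to four
   aggregated features, concatenated with age and sex, and passed through a
   final linear layer.
3. ``resnet_recurrent`` — same trunk; a convolution merges the lead dimension,
   then two stacked LSTM layers and a linear head.
4. ``rnn`` — only the first 5 s of signal, max-pooled (pool size 4) along
   time, fed to two stacked LSTM layers, dropout and a linear head.
5. ``scattering_mlp`` — per-lead wavelet scattering coefficients (invariance
   5 s, filter banks of 8 and 2 wavelets per octave) per time interval, a
   small MLP scoring each interval, scores averaged over intervals.
6. ``mlr`` — multivariate logistic regression on discrete waveform features
   plus age and sex; rows with missing features are discarded and reported.

Training (models 1-5): Adam on binary cross-entropy, Gaussian input noise
(sigma 0.1) after each dropout layer as regularisation, early stopping when
the validation loss makes no new minimum for six consecutive epochs, and
restoration of the best-validation-epoch weights.

Residual-block internals (kernel sizes 8/5/3, batch norm, ReLU, 1x1 projection
shortcut) follow the standard time-series residual network convention.  The
``reduced`` scale — small filter counts on 25 Hz decimated signals — is the
configuration exercised by the test suite; ``full`` scale keeps 128/256/256
filters at 500 Hz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor, no_grad
from .scattering import ScatteringConfig, multichannel_scattering
from .synthetic_data import ConfigurationError, ECGRecord

ARCHITECTURES = ("resnet", "resnet_demo", "resnet_recurrent", "rnn",
                 "scattering_mlp", "mlr")

DEFAULT_MLR_FEATURES = ("p_wave_duration_ms", "pr_interval_ms", "mean_rr_ms",
                        "pq_segment_level_uv", "age_years", "sex")


@dataclass(frozen=True)
class AFScore:
    ecg_id: str
    model_id: str
    score: float


@dataclass
class ModelConfig:
    architecture: str = "resnet"
    scale: str = "reduced"                 # {"reduced", "full"}
    filters: tuple[int, int, int] | None = None
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)
    gaussian_noise_sigma: float = 0.1
    dropout: float = 0.3
    pool_between_blocks: int | None = None   # temporal pool after blocks 1-2
    rnn_pool_size: int = 4
    rnn_input_seconds: float = 5.0
    scattering: ScatteringConfig = field(default_factory=ScatteringConfig)
    lstm_hidden: int | None = None
    mlp_hidden: tuple[int, ...] = (64, 32)
    demo_features: int = 4
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    early_stopping_patience: int = 6
    input_fs: float | None = None          # model-side decimation target (Hz)
    mlr_features: tuple[str, ...] = DEFAULT_MLR_FEATURES
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.scale not in ("reduced", "full"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.filters is None:
            self.filters = (128, 256, 256) if self.scale == "full" else (8, 16, 16)
        if self.lstm_hidden is None:
            if self.scale == "full":
                self.lstm_hidden = 64
            else:
                # the rnn digests raw pooled samples rather than trunk
                # features and needs more recurrent state
                self.lstm_hidden = 24 if self.architecture == "rnn" else 16
        if self.input_fs is None:
            if self.scale == "full":
                self.input_fs = 500.0
            else:
                # the rnn max-pools raw samples (no convolution first); at
                # 25 Hz that would erase the P wave entirely
                self.input_fs = 125.0 if self.architecture == "rnn" else 25.0
        if self.pool_between_blocks is None:
            self.pool_between_blocks = 1 if self.scale == "full" else 2

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ModelData:
    """Assembled model inputs for one split part."""

    X: np.ndarray                   # (N, 12, L) float32, decimated mV
    y: np.ndarray                   # (N,) float32 labels, AF=1
    age: np.ndarray                 # (N,) years (nan if unknown)
    sex: np.ndarray                 # (N,) 0=M, 1=F
    ecg_ids: list[str]
    patient_ids: list[str]
    fs: float
    features: pd.DataFrame | None = None     # discrete features (for MLR)
    scattering: np.ndarray | None = None     # cached (N, frames, D)

    def __len__(self) -> int:
        return len(self.ecg_ids)

    def subset(self, idx: Sequence[int]) -> "ModelData":
        idx = np.asarray(idx, dtype=int)
        return ModelData(
            X=self.X[idx], y=self.y[idx], age=self.age[idx], sex=self.sex[idx],
            ecg_ids=[self.ecg_ids[i] for i in idx],
            patient_ids=[self.patient_ids[i] for i in idx], fs=self.fs,
            features=(self.features.iloc[idx].reset_index(drop=True)
                      if self.features is not None else None),
            scattering=(self.scattering[idx] if self.scattering is not None
                        else None))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------

class _ResidualBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, kernels, rng):
        k1, k2, k3 = kernels
        self.c1 = nn.Conv1d(in_ch, out_ch, k1, rng)
        self.n1 = nn.BatchNorm1d(out_ch)
        self.c2 = nn.Conv1d(out_ch, out_ch, k2, rng)
        self.n2 = nn.BatchNorm1d(out_ch)
        self.c3 = nn.Conv1d(out_ch, out_ch, k3, rng)
        self.n3 = nn.BatchNorm1d(out_ch)
        self.proj = nn.Conv1d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None
        self.nproj = nn.BatchNorm1d(out_ch) if self.proj is not None else None

    def __call__(self, x, train: bool):
        h = nn.relu(self.n1(self.c1(x), train))
        h = nn.relu(self.n2(self.c2(h), train))
        h = self.n3(self.c3(h), train)
        sc = x if self.proj is None else self.nproj(self.proj(x), train)
        return nn.relu(nn.add(h, sc))


class _ResNetTrunk(nn.Module):
    """Per-lead temporal residual trunk: (N, 12, L) -> (N, C, 12, L)."""

    def __init__(self, config: ModelConfig, rng):
        f1, f2, f3 = config.filters
        self.blocks = [
            _ResidualBlock(1, f1, config.kernel_sizes, rng),
            _ResidualBlock(f1, f2, config.kernel_sizes, rng),
            _ResidualBlock(f2, f3, config.kernel_sizes, rng),
        ]
        self.dropout = config.dropout
        self.sigma = config.gaussian_noise_sigma
        self.pool = config.pool_between_blocks
        self.out_channels = f3

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        N, n_leads, L = x.shape
        h = nn.reshape(x, (N * n_leads, 1, L))
        for i, block in enumerate(self.blocks):
            h = block(h, train)
            h = nn.dropout(h, self.dropout, rng, train)
            h = nn.gaussian_noise(h, self.sigma, rng, train)
            if self.pool > 1 and i < len(self.blocks) - 1:
                h = nn.max_pool1d(h, self.pool)
        C = self.out_channels
        Lt = h.shape[-1]
        h = nn.reshape(h, (N, n_leads, C, Lt))
        return nn.transpose(h, (0, 2, 1, 3))  # (N, C, leads, time)


class _BaseNet(nn.Module):
    needs_demographics = False
    uses_scattering = False

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    def forward(self, data: ModelData, idx: np.ndarray, train: bool) -> Tensor:
        raise NotImplementedError

    def predict(self, data: ModelData, batch_size: int = 128) -> np.ndarray:
        """AF scores in [0, 1]; deterministic (noise/dropout inactive)."""
        scores = np.empty(len(data))
        with no_grad():
            for lo in range(0, len(data), batch_size):
                idx = np.arange(lo, min(lo + batch_size, len(data)))
                logit = self.forward(data, idx, train=False)
                scores[idx] = 1.0 / (1.0 + np.exp(-logit.data.reshape(-1)))
        return scores


class ResNetClassifier(_BaseNet):
    architecture = "resnet"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = self.rng
        self.trunk = _ResNetTrunk(config, rng)
        self.head = nn.Dense(self.trunk.out_channels, 1, rng)
        self._last_maps: np.ndarray | None = None

    def forward(self, data, idx, train):
        x = Tensor(data.X[idx])
        maps = self.trunk(x, train, self.rng)           # (N, C, leads, L)
        if not train:
            self._last_maps = maps.data
        pooled = nn.reduce_mean(maps, axis=(2, 3))      # (N, C)
        return self.head(pooled)

    def activation_maps(self, data: ModelData, idx) -> np.ndarray:
        """Last-block (time, lead) maps per channel, needed for CAM."""
        with no_grad():
            self.forward(data, np.asarray(idx), train=False)
        return self._last_maps

    @property
    def cam_weights(self) -> np.ndarray:
        return self.head.w.data.reshape(-1)

    def cam_alignment(self) -> tuple[int, float]:
        """(total stride, accumulated group delay in input samples).

        Even kernels pad asymmetrically ('same' with one extra trailing
        sample), delaying each stage's output by half a sample at that
        stage's resolution; pooling compounds the delay downstream.
        """
        p = self.config.pool_between_blocks
        total_stride = p * p
        shift = sum(0.5 * (p ** block)
                    for block in range(3)
                    for k in self.config.kernel_sizes if k % 2 == 0)
        return total_stride, shift


class ResNetDemo(_BaseNet):
    architecture = "resnet_demo"
    needs_demographics = True

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = self.rng
        self.trunk = _ResNetTrunk(config, rng)
        self.reduce = nn.Dense(self.trunk.out_channels, config.demo_features, rng)
        self.head = nn.Dense(config.demo_features + 2, 1, rng)

    def forward(self, data, idx, train):
        if np.isnan(data.age[idx]).any():
            raise ConfigurationError("resnet_demo requires age for every record")
        x = Tensor(data.X[idx])
        maps = self.trunk(x, train, self.rng)
        pooled = nn.reduce_mean(maps, axis=(2, 3))
        feats = self.reduce(pooled)                      # four aggregated features
        demo = Tensor(np.stack([data.age[idx] / 100.0, data.sex[idx]],
                               axis=1).astype(nn.DTYPE))
        return self.head(nn.concat([feats, demo], axis=1))


class ResNetRecurrent(_BaseNet):
    architecture = "resnet_recurrent"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = self.rng
        self.trunk = _ResNetTrunk(config, rng)
        C = self.trunk.out_channels
        self.merge = nn.Conv1d(12 * C, C, 3, rng)   # combines the lead dimension
        self.pool = config.rnn_pool_size
        H = config.lstm_hidden
        self.lstm1 = nn.LSTM(C, H, rng)
        self.lstm2 = nn.LSTM(H, H, rng)
        self.head = nn.Dense(H, 1, rng)

    def forward(self, data, idx, train):
        x = Tensor(data.X[idx])
        maps = self.trunk(x, train, self.rng)            # (N, C, leads, L)
        N, C, n_leads, L = maps.shape
        h = nn.reshape(maps, (N, C * n_leads, L))
        h = self.merge(h)                                # (N, C, L)
        h = nn.max_pool1d(h, self.pool)
        h = nn.transpose(h, (0, 2, 1))                   # (N, T, C)
        h = self.lstm2(self.lstm1(h))
        # time-averaged readout: propagates gradient to every step
        return self.head(nn.reduce_mean(h, axis=1))


class RNNModel(_BaseNet):
    architecture = "rnn"

    def __init__(self, config: ModelConfig):
        super().__init__(config)
        rng = self.rng
        H = config.lstm_hidden
        self.pool = config.rnn_pool_size
        self.lstm1 = nn.LSTM(12, H, rng)
        self.lstm2 = nn.LSTM(H, H, rng)
        self.head = nn.Dense(H, 1, rng)
        self.dropout = config.dropout

    def forward(self, data, idx, train):
        n_keep = int(self.config.rnn_input_seconds * data.fs)
        x = Tensor(data.X[idx][:, :, :n_keep])           # first 5 s only
        h = nn.max_pool1d(x, self.pool)                  # (N, 12, T)
        h = nn.transpose(h, (0, 2, 1))                   # (N, T, 12)
        h = self.lstm2(self.lstm1(h))
        pooled = nn.reduce_mean(h, axis=1)               # time-averaged readout
        pooled = nn.dropout(pooled, self.dropout, self.rng, train)
        return self.head(pooled)


class ScatteringMLP(_BaseNet):
    """MLP over per-interval scattering coefficients; interval scores averaged."""

    architecture = "scattering_mlp"
    uses_scattering = True

    def __init__(self, config: ModelConfig, n_coeffs: int):
        super().__init__(config)
        rng = self.rng
        widths = (n_coeffs,) + tuple(config.mlp_hidden)
        self.layers = [nn.Dense(a, b, rng) for a, b in zip(widths, widths[1:])]
        self.head = nn.Dense(widths[-1], 1, rng)
        self.dropout = config.dropout

    def _frame_logits(self, feats: np.ndarray, train: bool) -> Tensor:
        N, F, D = feats.shape
        h = Tensor(feats.reshape(N * F, D).astype(nn.DTYPE))
        for layer in self.layers:
            h = nn.relu(layer(h))
            h = nn.dropout(h, self.dropout, self.rng, train)
        return nn.reshape(self.head(h), (N, F))

    def forward(self, data, idx, train):
        feats = ensure_scattering(data, self.config)[idx]
        return self._frame_logits(feats, train)          # (N, frames)

    def predict(self, data, batch_size: int = 256) -> np.ndarray:
        feats = ensure_scattering(data, self.config)
        scores = np.empty(len(data))
        with no_grad():
            for lo in range(0, len(data), batch_size):
                idx = np.arange(lo, min(lo + batch_size, len(data)))
                logits = self._frame_logits(feats[idx], train=False).data
                scores[idx] = (1.0 / (1.0 + np.exp(-logits))).mean(axis=1)
        return scores


def ensure_scattering(data: ModelData, config: ModelConfig) -> np.ndarray:
    """Compute (and cache on ``data``) the per-record scattering features."""
    if data.scattering is None:
        mats = [multichannel_scattering(x, data.fs, config.scattering)
                for x in data.X]
        raw = np.stack(mats)
        # fixed compressive rescaling: coefficient magnitudes span orders of
        # magnitude, and a dataset-independent transform keeps train/test
        # features on an identical scale
        data.scattering = np.log1p(100.0 * raw).astype(np.float32)
    return data.scattering


# ---------------------------------------------------------------------------
# multivariate logistic regression
# ---------------------------------------------------------------------------

@dataclass
class MLRModel:
    """Logistic regression on discrete ECG features (the 'distance' feature of
    the source regression model is deliberately not used)."""

    feature_names: tuple[str, ...] = DEFAULT_MLR_FEATURES
    params: pd.Series | None = None
    bse: pd.Series | None = None
    converged: bool = True
    dropped_rows: list = field(default_factory=list)
    architecture: str = "mlr"
    needs_demographics = False

    def _design(self, table: pd.DataFrame) -> pd.DataFrame:
        X = table.loc[:, list(self.feature_names)].copy()
        if "sex" in X.columns and X["sex"].dtype == object:
            X["sex"] = (X["sex"] == "F").astype(float)
        return X.astype(float)

    def fit(self, table: pd.DataFrame, labels: np.ndarray) -> "MLRModel":
        import statsmodels.api as sm

        X = self._design(table)
        ok = ~X.isna().any(axis=1)
        self.dropped_rows = list(table.index[~ok])
        X = X[ok]
        y = np.asarray(labels, dtype=float)[np.asarray(ok)]
        design = sm.add_constant(X, has_constant="add")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            self.converged = bool(res.mle_retvals.get("converged", False))
            self.params = res.params
            self.bse = res.bse
        except Exception:
            # (quasi-)separated or singular design: ridge-regularised fallback
            from sklearn.linear_model import LogisticRegression

            clf = LogisticRegression(C=1e3, max_iter=1000).fit(X, y)
            self.converged = False
            self.params = pd.Series(
                np.concatenate([clf.intercept_, clf.coef_[0]]),
                index=["const"] + list(X.columns))
            self.bse = None
        if not self.converged:
            import warnings

            warnings.warn("MLR fit did not fully converge "
                          "(possible separation); coefficients regularised",
                          RuntimeWarning, stacklevel=2)
        return self

    def predict_table(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(scores with NaN for skipped rows, boolean mask of scored rows)."""
        import statsmodels.api as sm

        X = self._design(table)
        ok = ~X.isna().any(axis=1)
        design = sm.add_constant(X[ok], has_constant="add")
        design = design.reindex(columns=self.params.index, fill_value=1.0)
        z = np.asarray(design @ self.params, dtype=float)
        scores = np.full(len(table), np.nan)
        scores[np.asarray(ok)] = 1.0 / (1.0 + np.exp(-z))
        return scores, np.asarray(ok)

    def predict(self, data: ModelData, batch_size: int = 0) -> np.ndarray:
        if data.features is None:
            raise ConfigurationError("mlr requires assembled discrete features")
        scores, _ = self.predict_table(data.features)
        return scores


def fit_mlr(features_table: pd.DataFrame, labels,
            feature_names: Sequence[str] = DEFAULT_MLR_FEATURES) -> MLRModel:
    """Fit the logistic model, discarding (and recording) incomplete rows."""
    model = MLRModel(feature_names=tuple(feature_names))
    return model.fit(features_table, np.asarray(labels))


# ---------------------------------------------------------------------------
# factory / training
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, n_scattering_coeffs: int | None = None):
    """Instantiate the predictor named by ``config.architecture``."""
    if config.architecture == "resnet":
        return ResNetClassifier(config)
    if config.architecture == "resnet_demo":
        return ResNetDemo(config)
    if config.architecture == "resnet_recurrent":
        return ResNetRecurrent(config)
    if config.architecture == "rnn":
        return RNNModel(config)
    if config.architecture == "scattering_mlp":
        if n_scattering_coeffs is None:
            raise ConfigurationError(
                "scattering_mlp needs n_scattering_coeffs (12 * per-lead count)")
        return ScatteringMLP(config, n_scattering_coeffs)
    if config.architecture == "mlr":
        return MLRModel(feature_names=config.mlr_features)
    raise ConfigurationError(config.architecture)


def _epoch_loss(model, data: ModelData, batch_size: int) -> float:
    total, n = 0.0, 0
    with no_grad():
        for lo in range(0, len(data), batch_size):
            idx = np.arange(lo, min(lo + batch_size, len(data)))
            logits = model.forward(data, idx, train=False)
            y = data.y[idx]
            if logits.data.ndim == 2 and logits.data.shape[1] > 1:
                y = np.repeat(y[:, None], logits.data.shape[1], axis=1)
            loss = nn.bce_with_logits(logits, y.reshape(logits.data.shape))
            total += float(loss.data) * len(idx)
            n += len(idx)
    return total / max(n, 1)


def train(model, train_data: ModelData, val_data: ModelData,
          config: ModelConfig | None = None) -> TrainHistory:
    """Mini-batch training with patience-6 early stopping on validation loss.

    Stops after the validation loss has failed to set a new minimum for six
    consecutive epochs (or at ``max_epochs``) and restores the weights of the
    best validation epoch.
    """
    config = config or model.config
    if len(train_data) == 0 or len(val_data) == 0:
        raise ConfigurationError("empty training or validation split")
    if model.architecture == "mlr":
        raise ConfigurationError("mlr is fitted with fit_mlr, not train()")
    rng = np.random.default_rng(config.seed + 1)
    model.rng = np.random.default_rng(config.seed + 2)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    history = TrainHistory()
    best_state = model.state()
    bad = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_data))
        total, n = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = model.forward(train_data, idx, train=True)
            y = train_data.y[idx]
            if logits.data.ndim == 2 and logits.data.shape[1] > 1:
                y = np.repeat(y[:, None], logits.data.shape[1], axis=1)
            loss = nn.bce_with_logits(logits, y.reshape(logits.data.shape))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            n += len(idx)
        history.train_loss.append(total / n)
        val_loss = _epoch_loss(model, val_data, config.batch_size)
        history.val_loss.append(val_loss)
        if val_loss < history.best_val_loss:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = model.state()
            bad = 0
        else:
            bad += 1
            if bad >= config.early_stopping_patience:
                history.stopped_early = True
                break
    model.load_state(best_state)
    return history


def predict_scores(model, data: ModelData,
                   model_id: str | None = None) -> tuple[list[AFScore], list[str]]:
    """Per-ECG AF scores; MLR rows with missing features are skipped and listed."""
    model_id = model_id or model.architecture
    raw = model.predict(data)
    scores, skipped = [], []
    for i, ecg_id in enumerate(data.ecg_ids):
        if np.isnan(raw[i]):
            skipped.append(ecg_id)
        else:
            scores.append(AFScore(ecg_id=ecg_id, model_id=model_id,
                                  score=float(raw[i])))
    return scores, skipped


# ---------------------------------------------------------------------------
# rhythm double-confirmation classifier
# ---------------------------------------------------------------------------

def make_rhythm_confirmer(seed: int = 0):
    """Small AF-vs-sinus rhythm classifier used to double-check AF labels.

    Trained on synthetic rhythm examples using two rhythm-level statistics
    (RR-interval coefficient of variation and detected P waves per QRS); the
    returned callable maps an ECGRecord to P(atrial fibrillation) in [0, 1].
    """
    from sklearn.linear_model import LogisticRegression

    from .synthetic_data import Patient, SimulationConfig, synthesize_ecg

    config = SimulationConfig(noise_white_mv=0.02, baseline_wander_mv=0.02)
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    patient = Patient("RC001", "M", birth_day=0, group="SR")
    for i in range(30):
        rhythm = "af" if i % 2 else "sinus"
        rec = synthesize_ecg(patient, 60 * 365, rhythm, "none", config,
                             seed=int(rng.integers(1, 2**31 - 1)))
        rows.append(_rhythm_stats(rec))
        labels.append(1 if rhythm == "af" else 0)
    clf = LogisticRegression().fit(np.array(rows), np.array(labels))

    def confirmer(record: ECGRecord) -> float:
        return float(clf.predict_proba([_rhythm_stats(record)])[0, 1])

    return confirmer


def _rhythm_stats(record: ECGRecord) -> list[float]:
    from scipy.signal import find_peaks

    sig = record.signals[1]  # lead II
    fs = record.sampling_rate
    height = 0.5 * np.max(sig) if np.max(sig) > 0 else None
    r_idx, _ = find_peaks(sig, height=height, distance=int(0.3 * fs))
    if r_idx.size < 3:
        return [1.0, 0.0]
    rr = np.diff(r_idx) / fs
    rr_cv = float(np.std(rr) / np.mean(rr))
    n_p = 0
    for r in r_idx:
        lo, hi = max(r - int(0.25 * fs), 0), r - int(0.08 * fs)
        if hi <= lo:
            continue
        window = sig[lo:hi]
        if window.max() - np.median(window) > 0.06:
            n_p += 1
    return [rr_cv, n_p / r_idx.size]
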