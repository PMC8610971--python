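"""Model contracts: score ranges, architecture structure, training protocol,
logistic-regression calibration and recovery."""

import numpy as np
import pandas as pd
import pytest

from afpredict import nn
from afpredict.models import (ModelConfig, ModelData, build_model,
                              ensure_scattering, fit_mlr, predict_scores,
                              train)
from afpredict.synthetic_data import ConfigurationError


def _random_data(rng, n=8, L=250, fs=25.0, seed_labels=True):
    return ModelData(
        X=rng.normal(size=(n, 12, L)).astype(np.float32),
        y=rng.integers(0, 2, n).astype(np.float32),
        age=np.full(n, 60.0), sex=rng.integers(0, 2, n).astype(float),
        ecg_ids=[f"E{i}" for i in range(n)],
        patient_ids=[f"P{i}" for i in range(n)], fs=fs,
        features=pd.DataFrame({
            "p_wave_duration_ms": rng.normal(110, 5, n),
            "pr_interval_ms": rng.normal(160, 5, n),
            "mean_rr_ms": rng.normal(900, 40, n),
            "pq_segment_level_uv": rng.normal(0, 5, n),
            "age_years": np.full(n, 60.0),
            "sex": rng.integers(0, 2, n).astype(float)}))


@pytest.mark.parametrize("arch", ["resnet", "resnet_demo", "resnet_recurrent",
                                  "rnn", "scattering_mlp"])
def test_scores_in_unit_interval_and_deterministic(arch, rng):
    data = _random_data(rng)
    cfg = ModelConfig(architecture=arch, seed=3)
    n_coeffs = None
    if arch == "scattering_mlp":
        n_coeffs = ensure_scattering(data, cfg).shape[-1]
    model = build_model(cfg, n_scattering_coeffs=n_coeffs)
    s1 = model.predict(data)
    s2 = model.predict(data)
    assert np.all((s1 >= 0) & (s1 <= 1)) and np.all(np.isfinite(s1))
    assert np.array_equal(s1, s2)


def test_rnn_ignores_signal_after_five_seconds(rng):
    data = _random_data(rng, L=250, fs=25.0)
    model = build_model(ModelConfig(architecture="rnn", seed=1))
    before = model.predict(data)
    tampered = _random_data(rng)
    tampered.X = data.X.copy()
    tampered.X[:, :, 125:] = rng.normal(size=(8, 12, 125))  # after t = 5 s
    assert np.array_equal(before, model.predict(tampered))


def test_resnet_block_filter_counts_at_full_scale():
    model = build_model(ModelConfig(architecture="resnet", scale="full"))
    counts = [block.c1.w.data.shape[0] for block in model.trunk.blocks]
    assert counts == [128, 256, 256]
    for block in model.trunk.blocks:
        assert block.c1.w.data.shape[2] == 8
        assert block.c2.w.data.shape[2] == 5
        assert block.c3.w.data.shape[2] == 3


def test_resnet_is_cam_compatible(rng):
    """Penultimate representation: per-channel (time, lead) maps -> GAP ->
    one linear layer, the structure class activation mapping requires."""
    data = _random_data(rng)
    model = build_model(ModelConfig(architecture="resnet", seed=0))
    maps = model.activation_maps(data, [0, 1])
    C = model.trunk.out_channels
    assert maps.shape[0] == 2 and maps.shape[1] == C
    assert maps.shape[2] == 12                       # lead axis preserved
    assert model.head.w.data.shape == (C, 1)
    pooled = maps.mean(axis=(2, 3))
    logits = pooled @ model.head.w.data + model.head.b.data
    scores = 1 / (1 + np.exp(-logits[:, 0]))
    assert np.allclose(scores, model.predict(data)[:2], atol=1e-5)


def test_demo_model_requires_age(rng):
    data = _random_data(rng)
    data.age[:] = np.nan
    model = build_model(ModelConfig(architecture="resnet_demo", seed=0))
    with pytest.raises(ConfigurationError):
        model.predict(data)


class _StubModel:
    """Fixed-output model for exercising the early-stopping rule."""

    architecture = "stub"

    def __init__(self):
        self.w = nn.Tensor(np.zeros(1), requires_grad=True)
        self.rng = np.random.default_rng(0)

    def parameters(self):
        return [self.w]

    def state(self):
        return [self.w.data.copy()]

    def load_state(self, state):
        self.w.data = state[0].copy()

    def forward(self, data, idx, train):
        return nn.mul(self.w, nn.Tensor(np.zeros((len(idx), 1))))


def test_early_stopping_after_exactly_patience_plus_one_epochs(rng):
    # constant validation loss: epoch 1 sets the minimum, epochs 2-7 fail to
    # improve, training halts after 1 + 6 epochs
    data = _random_data(rng, n=6)
    model = _StubModel()
    cfg = ModelConfig(architecture="resnet", max_epochs=50,
                      early_stopping_patience=6, batch_size=4)
    history = train(model, data, data, cfg)
    assert history.n_epochs == 7
    assert history.stopped_early
    assert history.best_epoch == 0


def test_training_is_seed_reproducible(rng):
    data = _random_data(rng, n=24)
    val = _random_data(rng, n=12)
    cfg = ModelConfig(architecture="rnn", max_epochs=2, seed=9)
    m1 = build_model(cfg)
    train(m1, data, val, cfg)
    m2 = build_model(cfg)
    train(m2, data, val, cfg)
    assert np.array_equal(m1.predict(val), m2.predict(val))


def test_empty_split_rejected(rng):
    data = _random_data(rng, n=4)
    empty = data.subset([])
    model = build_model(ModelConfig(architecture="rnn"))
    with pytest.raises(ConfigurationError):
        train(model, empty, data, ModelConfig(architecture="rnn"))


# ---------------------------------------------------------------------------
# multivariate logistic regression
# ---------------------------------------------------------------------------

def _mlr_table(rng, n, beta=None):
    X = pd.DataFrame({
        "p_wave_duration_ms": rng.normal(0, 1, n),
        "pr_interval_ms": rng.normal(0, 1, n),
        "mean_rr_ms": rng.normal(0, 1, n),
        "pq_segment_level_uv": rng.normal(0, 1, n),
        "age_years": rng.normal(0, 1, n),
        "sex": rng.integers(0, 2, n).astype(float)})
    if beta is None:
        logits = np.zeros(n)
    else:
        logits = X.to_numpy() @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    return X, y


def test_mlr_null_calibration(rng):
    # labels independent of features: standardized coefficients stay small
    X, y = _mlr_table(rng, 2000)
    model = fit_mlr(X, y)
    z = (model.params.drop("const") / model.bse.drop("const")).abs()
    assert (z < 3).sum() >= 5


def test_mlr_recovers_planted_log_odds(rng):
    beta = np.array([2.0, 0, 0, 0, 0, 0])
    X, y = _mlr_table(rng, 4000, beta)
    model = fit_mlr(X, y)
    assert 1.5 <= model.params["p_wave_duration_ms"] <= 2.5


def test_mlr_drops_and_reports_missing_rows(rng):
    X, y = _mlr_table(rng, 50)
    X.loc[7, "pr_interval_ms"] = np.nan
    X.loc[13, "mean_rr_ms"] = np.nan
    model = fit_mlr(X, y)
    assert model.dropped_rows == [7, 13]
    scores, ok = model.predict_table(X)
    assert np.isnan(scores[7]) and np.isnan(scores[13])
    assert ok.sum() == 48


def test_all_six_models_discriminate_and_fusion_holds(planted_registry):
    """On the planted-effect cohort every architecture separates the classes
    (ECG-level AUC > 0.7) and score fusion is no worse than the weakest
    member."""
    from afpredict.cohort import SplitSizes, build_scenario_split
    from afpredict.evaluation import fuse, roc_auc_ci
    from afpredict.models import ensure_scattering
    from afpredict.pipeline import assemble_model_data

    sizes = SplitSizes(train_af_ecgs=200, val_af_ecgs=40, test_af_patients=20,
                       test_sr_patients=40)
    split = build_scenario_split(planted_registry, "random_sampling", sizes,
                                 seed=8)
    aucs = {}
    tables = {}
    label_of = {}
    # the recurrent models converge more slowly than the convolutional trunk
    epochs = {"rnn": 45, "scattering_mlp": 25}
    for arch in ("resnet", "resnet_demo", "resnet_recurrent", "rnn",
                 "scattering_mlp", "mlr"):
        cfg = ModelConfig(architecture=arch, max_epochs=epochs.get(arch, 8),
                          seed=2)
        train_data = assemble_model_data(planted_registry, split.train, cfg)
        val_data = assemble_model_data(planted_registry, split.val, cfg)
        test_data = assemble_model_data(planted_registry, split.test, cfg)
        if arch == "mlr":
            model = fit_mlr(train_data.features, train_data.y)
        else:
            n_coeffs = None
            if arch == "scattering_mlp":
                n_coeffs = ensure_scattering(train_data, cfg).shape[-1]
            model = build_model(cfg, n_scattering_coeffs=n_coeffs)
            train(model, train_data, val_data, cfg)
        scores, _ = predict_scores(model, test_data)
        tables[arch] = scores
        label_of.update(zip(test_data.ecg_ids, test_data.y.astype(int)))
        aucs[arch], _ = roc_auc_ci([s.score for s in scores],
                                   [label_of[s.ecg_id] for s in scores])
    assert all(a > 0.7 for a in aucs.values()), aucs
    fused, _ = fuse(tables)
    auc_fused, _ = roc_auc_ci([s.score for s in fused],
                              [label_of[s.ecg_id] for s in fused])
    assert auc_fused >= min(aucs.values()), (auc_fused, aucs)


def test_predict_scores_reports_mlr_skips(rng):
    data = _random_data(rng, n=10)
    data.features.loc[2, "pr_interval_ms"] = np.nan
    data.features.loc[5, "pq_segment_level_uv"] = np.nan
    model = fit_mlr(data.features, data.y)
    scores, skipped = predict_scores(model, data)
    assert len(scores) == 8 and sorted(skipped) == ["E2", "E5"]
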