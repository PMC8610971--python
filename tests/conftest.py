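"""Shared fixtures.

The expensive fixtures (trained models on synthetic cohorts) are session-scoped
and shared across the evaluation, interpretability and acceptance tests; their
cohort sizes are the package's desk-scale study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

from afpredict.cohort import SplitSizes, assign_groups_and_index_dates
from afpredict.models import ModelConfig, make_rhythm_confirmer
from afpredict.pipeline import run_experiment
from afpredict.synthetic_data import (SimulationConfig, generate_registry,
                                      planted_effect_config)

# desk-scale study conditions shared by the benchmark fixtures
PLANTED_SIZES = SplitSizes(train_af_ecgs=300, val_af_ecgs=50,
                           test_af_patients=25, test_sr_patients=50)
SCENARIO_SIZES = SplitSizes(train_af_ecgs=400, val_af_ecgs=50,
                            test_af_patients=30, test_sr_patients=60)
REDUCED_RESNET = ModelConfig(architecture="resnet", max_epochs=8, seed=1)


def _confirmed_registry(config: SimulationConfig):
    registry = generate_registry(config)
    registry, report = assign_groups_and_index_dates(
        registry, make_rhythm_confirmer(0))
    return registry, report


@pytest.fixture(scope="session")
def small_registry():
    """A small confirmed registry for cohort-level tests (no training)."""
    registry, _ = _confirmed_registry(
        SimulationConfig(n_af_patients=40, n_sr_patients=260, seed=7))
    return registry


@pytest.fixture(scope="session")
def planted_registry():
    """Planted-effect cohort, delta_p = 0.4, identical age models per group."""
    registry, _ = _confirmed_registry(
        planted_effect_config(delta_p=0.4, n_af_patients=150,
                              n_sr_patients=600, seed=11))
    return registry


@pytest.fixture(scope="session")
def planted_result(planted_registry):
    """Reduced resnet trained on the planted-effect cohort (AUC benchmark)."""
    return run_experiment(planted_registry, "random_sampling", PLANTED_SIZES,
                          REDUCED_RESNET, seed=1, keep_test_data=True)


@pytest.fixture(scope="session")
def null_result():
    """Same protocol with delta_p = 1: the two classes are exchangeable."""
    registry, _ = _confirmed_registry(
        planted_effect_config(delta_p=1.0, n_af_patients=150,
                              n_sr_patients=600, seed=12))
    return run_experiment(registry, "random_sampling", PLANTED_SIZES,
                          REDUCED_RESNET, seed=2)


@pytest.fixture(scope="session")
def scenario_results():
    """Reduced resnet under the three SR-sampling scenarios of the
    age-confounded cohort (AF median 80 y vs SR 64 y, age trends active)."""
    registry, _ = _confirmed_registry(
        SimulationConfig(n_af_patients=200, n_sr_patients=3000, delta_p=0.85,
                         t_amp_age_slope=0.015, seed=21))
    config = REDUCED_RESNET.replace(max_epochs=6)
    out = {}
    for scenario in ("young_sr", "random_sampling", "balanced_age"):
        out[scenario] = run_experiment(registry, scenario, SCENARIO_SIZES,
                                       config, seed=5)
    out["registry"] = registry
    return out


@pytest.fixture(scope="session")
def v23_result():
    """Planted effect restricted to leads V2/V3 (attribution benchmark).

    Attribution needs finer temporal granularity than classification, so this
    model runs on 50 Hz inputs; the stronger effect size keeps the model well
    into its converged regime, where channel weights are discriminative and
    class activation maps localize.
    """
    registry, _ = _confirmed_registry(
        planted_effect_config(delta_p=0.2, n_af_patients=140,
                              n_sr_patients=500, seed=31,
                              class_effect_leads=("V2", "V3")))
    sizes = SplitSizes(train_af_ecgs=300, val_af_ecgs=50,
                       test_af_patients=25, test_sr_patients=50)
    config = ModelConfig(architecture="resnet", max_epochs=10, seed=1,
                         input_fs=50.0)
    return run_experiment(registry, "random_sampling", sizes, config, seed=3,
                          keep_test_data=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
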