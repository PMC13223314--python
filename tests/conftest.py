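"""Shared fixtures: small synthetic cohorts and trained models.

Everything is generated at session scope so expensive artifacts (cohorts,
a trained autoencoder) are built once and reused across test modules.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from semglearn.csae import build_csae, small_csae_config, train_csae
from semglearn.data import apply_scaler, fit_scaler, make_loso_folds, segment_cohort
from semglearn.nn import TrainConfig
from semglearn.synth import generate_cohort, reference_cohorts


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects x 6 gestures x 6 trials at desk scale (1 kHz, 1.5 s)."""
    config = replace(reference_cohorts(reduced=True)["easy6"],
                     n_subjects=3, seed=123)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_fold(tiny_cohort):
    """Standardized train/val/test split of the first LOSO fold."""
    batch = segment_cohort(tiny_cohort, 250.0, 125.0)
    plan = make_loso_folds(tiny_cohort)[0]
    src = batch.select(subjects=plan.source_subjects)
    train = src.select(trials=plan.source_train_trials)
    scaler = fit_scaler(train)
    return {
        "plan": plan,
        "batch": batch,
        "scaler": scaler,
        "train": apply_scaler(train, scaler),
        "val": apply_scaler(src.select(trials=plan.source_val_trials), scaler),
        "test": apply_scaler(src.select(trials=plan.source_test_trials), scaler),
        "target": batch.select(subjects=[plan.target_subject]),
    }


@pytest.fixture(scope="session")
def trained_ae(tiny_fold):
    """A briefly trained small autoencoder (enough to be meaningful)."""
    model = build_csae(small_csae_config(seed=7), (250, 2))
    tc = TrainConfig(max_epochs=8, early_stop_patience=8, learning_rate=2e-3)
    train_csae(model, tiny_fold["train"], tiny_fold["val"], tc)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
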