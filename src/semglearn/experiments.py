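"""Desk-scale reference experiments.

These functions run the full pipeline on the reduced presets (1 kHz, 1.5-s
trials, compact model) at fixed problem sizes chosen so a complete study —
pooled baseline, user adaptation, class expansion, architecture contrast and
the sparsity sweep — finishes on a single CPU in minutes.  Each experiment
evaluates one leave-one-subject-out fold per call (the fold index rotates
with the seed so repeated runs cover different target subjects), which is
the unit the cross-seed summaries aggregate over.

Both the test suite and the reproduction script build on these entry points
so that every reported number comes from one code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .baselines import build_fcae, train_fcae, train_rf_baseline
from .classifier import build_classifier, predict, small_classifier_config, train_classifier
from .csae import build_csae, r2_reconstruction, small_csae_config, train_csae
from .data import apply_scaler, fit_scaler, make_loso_folds, segment_cohort
from .evaluation import lambda_sweep, prf1, run_loso
from .nn import TrainConfig
from .synth import generate_cohort, reference_cohorts

WINDOW_MS = 250.0
STRIDE_MS = 125.0

#: Training schedules for desk-scale runs.
TC_AE = TrainConfig(max_epochs=30, early_stop_patience=8, learning_rate=2e-3)
TC_CLF = TrainConfig(max_epochs=200, early_stop_patience=30, learning_rate=2e-3)
#: Expansion Phase II: a quarter of the Phase-I rate.
TC_PHASE2 = TrainConfig(max_epochs=150, early_stop_patience=25,
                        learning_rate=5e-4)


def _cohort(preset: str, seed: int, n_subjects: int | None = None):
    config = replace(reference_cohorts(reduced=True)[preset], seed=seed)
    if n_subjects is not None:
        config = replace(config, n_subjects=n_subjects)
    return generate_cohort(config), config


def _fold_for(seed: int, n_subjects: int = 8) -> list[int]:
    return [seed % n_subjects]


def pooled_f1(seed: int) -> float:
    """Pooled-protocol micro-F1 on one ``easy6`` fold (seen-subject test)."""
    cohort, _ = _cohort("easy6", seed)
    report = run_loso(cohort, protocol="pooled",
                      csae_config=small_csae_config(),
                      clf_config=small_classifier_config(6),
                      tc_csae=TC_AE, tc_clf=TC_CLF, seed=seed,
                      folds=_fold_for(seed))
    return report.mean_micro_f1


def adaptation_f1(seed: int) -> dict:
    """Unseen-subject micro-F1 before/after few-shot calibration on one
    ``shifted6`` fold."""
    cohort, _ = _cohort("shifted6", seed)
    out = run_loso(cohort, protocol="adapt",
                   csae_config=small_csae_config(),
                   clf_config=small_classifier_config(6),
                   tc_csae=TC_AE, tc_clf=TC_CLF, seed=seed,
                   folds=_fold_for(seed))
    return {"pre": out["pre"].mean_micro_f1, "post": out["post"].mean_micro_f1}


def expansion_f1(seed: int) -> dict:
    """Phase I/II micro-F1 and the forgetting table on one ``easy10`` fold."""
    cohort, _ = _cohort("easy10", seed)
    out = run_loso(cohort, protocol="expand",
                   csae_config=small_csae_config(),
                   clf_config=small_classifier_config(6),
                   tc_csae=TC_AE, tc_clf=TC_CLF, tc_phase2=TC_PHASE2,
                   seed=seed, folds=_fold_for(seed))
    return {"base6": out["base6"].mean_micro_f1,
            "phase1": out["phase1"].mean_micro_f1,
            "phase2": out["phase2"].mean_micro_f1,
            "forgetting": out["forgetting"][0],
            "phase2_report": out["phase2"].fold_reports[0]}


def reconstruction_r2(seed: int) -> float:
    """Held-out-trial reconstruction R^2 of a trained CSAE on ``easy6``."""
    cohort, _ = _cohort("easy6", seed)
    batch = segment_cohort(cohort, WINDOW_MS, STRIDE_MS)
    plan = make_loso_folds(cohort)[seed % 8]
    src = batch.select(subjects=plan.source_subjects)
    train = src.select(trials=plan.source_train_trials)
    scaler = fit_scaler(train)
    T, C = batch.segments.shape[1:]
    model = build_csae(small_csae_config(seed=seed), (T, C))
    train_csae(model, apply_scaler(train, scaler),
               apply_scaler(src.select(trials=plan.source_val_trials), scaler),
               TC_AE)
    test = apply_scaler(src.select(trials=plan.source_test_trials), scaler)
    return r2_reconstruction(model, test)


def temporal_contrast(seed: int) -> dict:
    """CSAE-feature vs FCAE-feature classification on ``temporal2``.

    The two classes differ only in which channel's burst train leads, so the
    contrast isolates whether a feature extractor preserves temporal
    structure.  The convolutional path feeds the attention head; the
    flattened dense autoencoder's bottleneck feeds a random forest, the
    pairing used for flat feature vectors.
    """
    cohort, config = _cohort("temporal2", seed)
    batch = segment_cohort(cohort, WINDOW_MS, STRIDE_MS)
    plan = make_loso_folds(cohort)[seed % 8]
    src = batch.select(subjects=plan.source_subjects)
    train = src.select(trials=plan.source_train_trials)
    scaler = fit_scaler(train)

    def std(b):
        return apply_scaler(b, scaler)

    train_s = std(train)
    val_s = std(src.select(trials=plan.source_val_trials))
    test_s = std(src.select(trials=plan.source_test_trials))
    classes = list(config.gesture_names)
    T, C = batch.segments.shape[1:]

    ae = build_csae(small_csae_config(seed=seed), (T, C))
    train_csae(ae, train_s, val_s, TC_AE)
    clf = build_classifier(ae, small_classifier_config(2, seed=seed + 1), classes)
    train_classifier(clf, train_s, val_s, TC_CLF)
    _, labels = predict(clf, test_s)
    csae_f1 = prf1(test_s.labels, labels, classes).micro_f1

    fcae = build_fcae(T * C, seed=seed + 2)
    train_fcae(fcae, train_s, val_s, TC_AE,
               rng=np.random.default_rng(seed + 3))
    rf = train_rf_baseline(fcae.encode(train_s), train_s.labels, seed=seed + 4)
    fcae_f1 = prf1(test_s.labels, rf.predict(fcae.encode(test_s)),
                   classes).micro_f1
    return {"csae_f1": csae_f1, "fcae_f1": fcae_f1}


SPARSITY_LAMBDAS = (0.0, 1e-7, 1e-4, 1e-1)


def sparsity_curve(seed: int):
    """Lambda sweep on a 4-subject ``easy6`` cohort: per-lambda mean F1 and
    the fraction of near-zero bottleneck activations on the held-out trial."""
    cohort, _ = _cohort("easy6", seed, n_subjects=4)
    table, best = lambda_sweep(
        cohort, SPARSITY_LAMBDAS, [small_csae_config().latent_filters],
        csae_config=small_csae_config(),
        clf_config=small_classifier_config(6),
        tc_csae=TC_AE, tc_clf=TC_CLF, seed=seed, folds=[seed % 4])
    return table, best
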