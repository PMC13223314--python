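"""Transfer protocols: few-shot user calibration and incremental class expansion.

Two clinical needs are addressed on top of a trained classifier:

* **Few-shot user adaptation** — a model trained on a pool of subjects
  performs poorly on an unseen user (inter-subject variability).  Calibration
  fine-tunes only the highest-level decision layers (the two MLP stages and
  the softmax output) on a single calibration trial per gesture, with the
  encoder and the feature-producing head layers frozen.

* **Incremental class expansion** — the softmax output layer is replaced by
  a wider one; weights and biases of the original classes are copied into
  their corresponding units so their pre-softmax logits are preserved
  exactly, while new units start from fresh random initialization.  Training
  then proceeds in two phases: Phase I trains only the new output layer;
  Phase II unfreezes the classifier head (conv, attention, MLP, output) at a
  significantly lower learning rate.  The encoder stays frozen throughout.

Freeze plans are enforced bitwise: parameter groups marked frozen hash
identically before and after every training entry point.
"""

from __future__ import annotations

import copy
import warnings

import numpy as np
import pandas as pd

from .classifier import (
    ClassifierModel,
    _check_labels,
    _train_head,
    predict,
)
from .data import SegmentBatch
from .nn import Dense, TrainConfig

#: Few-shot calibration: only the MLP stages and the output layer adapt.
FINETUNE_PLAN = {"encoder": False, "layer_norm": False, "conv": False,
                 "attention": False, "mlp_fc": True, "output_softmax": True}
#: Expansion Phase I: only the new output layer trains.
PHASE1_PLAN = {"encoder": False, "layer_norm": False, "conv": False,
               "attention": False, "mlp_fc": False, "output_softmax": True}
#: Expansion Phase II: the classifier head (conv, attention, MLP, output)
#: is unfrozen; the encoder stays frozen.
PHASE2_PLAN = {"encoder": False, "layer_norm": False, "conv": True,
               "attention": True, "mlp_fc": True, "output_softmax": True}

_FROZEN_GROUPS_FINETUNE = tuple(g for g, t in FINETUNE_PLAN.items() if not t)


def _train_output_layer(model: ClassifierModel, train: SegmentBatch,
                        val: SegmentBatch, tc: TrainConfig,
                        rng: np.random.Generator) -> dict:
    """Phase-I training loop: everything below the output layer is frozen,
    so its input features are precomputed once and only the softmax layer's
    weights see gradients (dropout is not applied to the fixed features)."""
    from semglearn.classifier import CE_EPS, cross_entropy
    from semglearn.data import one_hot
    from semglearn.nn import Tensor, fit

    z_train = model.encoder.encode(train.segments)
    z_val = model.encoder.encode(val.segments)
    m_train = model.penultimate_features(z_train)
    m_val = model.penultimate_features(z_val)
    y_train = one_hot(train.labels, model.class_list)
    y_val = one_hot(val.labels, model.class_list)

    def batch_loss(idx):
        p = (Tensor(m_train[idx]) @ model.out.w + model.out.b).softmax(axis=-1)
        return -(Tensor(y_train[idx]) * p.clip_min(CE_EPS).log()).sum(axis=1).mean()

    def val_loss():
        logits = m_val @ model.out.w.data + model.out.b.data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return cross_entropy(e / e.sum(axis=1, keepdims=True), y_val)

    return fit(model, batch_loss, val_loss, len(m_train), tc, rng)


def few_shot_finetune(model: ClassifierModel, calib: SegmentBatch,
                      val: SegmentBatch, tc: TrainConfig,
                      rng: np.random.Generator | None = None) -> ClassifierModel:
    """Calibrate a trained classifier to a new user.

    ``calib`` and ``val`` must come from the target subject only (by the
    default split: trial 1 for calibration, trial 2 for validation).  Only
    the final fully-connected layers (both MLP stages and the output layer)
    update; all feature-producing parameters are bit-identical afterwards.
    """
    _check_labels(calib, model.class_list)
    _check_labels(val, model.class_list, require_k=1)
    before = model.group_digests()
    model.apply_freeze_plan(FINETUNE_PLAN)
    if rng is None:
        rng = np.random.default_rng(model.config.seed % (2**31))
    history = _train_head(model, calib, val, tc, rng)
    model.history = {"finetune": history}
    after = model.group_digests()
    changed = [g for g in _FROZEN_GROUPS_FINETUNE if before[g] != after[g]]
    if changed:  # defensive: should be unreachable
        raise RuntimeError(f"freeze contract violated for groups {changed}")
    return model


def expand_classes(model6: ClassifierModel, new_class_list: list[str],
                   seed: int | None = None) -> ClassifierModel:
    """Widen the softmax output layer to ``new_class_list``.

    Every old class must appear in the new list; its output weights and bias
    are copied into the corresponding new unit, so old-class pre-softmax
    logits are exactly preserved.  Units for new classes are freshly
    He-Normal initialized under ``seed``.  All other parameters carry over
    unchanged (the returned model is an independent copy).
    """
    new_class_list = [str(c) for c in new_class_list]
    missing = [c for c in model6.class_list if c not in new_class_list]
    if missing:
        raise ValueError(f"old classes {missing} missing from the new class list")
    if len(set(new_class_list)) != len(new_class_list):
        raise ValueError("new class list contains duplicates")
    if seed is None:
        seed = model6.config.seed + 1
    model10 = copy.deepcopy(model6)
    model10.config = copy.deepcopy(model6.config)
    model10.config.n_classes = len(new_class_list)
    model10.config.seed = seed
    model10.class_list = new_class_list
    d_in = model6.out.w.data.shape[0]
    rng = np.random.default_rng(seed % (2**31))
    new_out = Dense(d_in, len(new_class_list), rng)
    for j_old, cls in enumerate(model6.class_list):
        j_new = new_class_list.index(cls)
        new_out.w.data[:, j_new] = model6.out.w.data[:, j_old]
        new_out.b.data[j_new] = model6.out.b.data[j_old]
    model10.out = new_out
    model10.history = {}
    return model10


def two_phase_train(model10: ClassifierModel, train: SegmentBatch,
                    val: SegmentBatch, tc1: TrainConfig, tc2: TrainConfig,
                    test: SegmentBatch | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ClassifierModel, dict]:
    """Two-phase training after class expansion.

    Phase I trains the new output layer only and restores its best
    checkpoint; Phase II unfreezes the head at ``tc2.learning_rate``
    (expected well below ``tc1.learning_rate``).  If ``test`` is given, the
    held-out micro-F1 after each phase is recorded in the returned info.
    """
    from .evaluation import prf1

    _check_labels(train, model10.class_list)
    _check_labels(val, model10.class_list, require_k=1)
    if tc2.learning_rate >= tc1.learning_rate:
        warnings.warn(
            "Phase II learning rate is not lower than Phase I — deviating "
            "from the staged protocol", RuntimeWarning, stacklevel=2)
    if rng is None:
        rng = np.random.default_rng(model10.config.seed % (2**31))
    info: dict = {}

    model10.apply_freeze_plan(PHASE1_PLAN)
    info["phase1_history"] = _train_output_layer(model10, train, val, tc1, rng)
    if test is not None:
        _, labels = predict(model10, test)
        info["phase1_report"] = prf1(test.labels, labels, model10.class_list)

    model10.apply_freeze_plan(PHASE2_PLAN)
    # Phase II refines an already-converged solution at a low rate; dropout
    # would only perturb it away from the optimum, so it is suspended here.
    saved_dropout = model10.config.dropout
    model10.config.dropout = 0.0
    try:
        info["phase2_history"] = _train_head(model10, train, val, tc2, rng)
    finally:
        model10.config.dropout = saved_dropout
    if test is not None:
        _, labels = predict(model10, test)
        info["phase2_report"] = prf1(test.labels, labels, model10.class_list)

    model10.history = {"phase1": info["phase1_history"],
                       "phase2": info["phase2_history"]}
    return model10, info


def forgetting_report(model6: ClassifierModel, model10: ClassifierModel,
                      test6: SegmentBatch) -> pd.DataFrame:
    """Per-class F1 on the original classes before and after expansion.

    ``test6`` must contain only original classes.  The expanded model is
    scored twice: over its full output (new classes may absorb errors) and
    restricted to the original classes' logits.  Columns: f1_before,
    f1_after, f1_after_restricted, and the corresponding deltas.
    """
    from .evaluation import prf1

    old = [str(c) for c in model6.class_list]
    extra = set(map(str, test6.labels)) - set(old)
    if extra:
        raise ValueError(f"test6 contains non-original classes {sorted(extra)}")

    _, labels6 = predict(model6, test6)
    rep_before = prf1(test6.labels, labels6, old)

    _, labels10 = predict(model10, test6)
    rep_after = prf1(test6.labels, labels10, model10.class_list)

    logits = model10.logits(test6)
    old_cols = [model10.class_list.index(c) for c in old]
    restricted = np.array([old[i] for i in logits[:, old_cols].argmax(axis=1)],
                          dtype=object)
    rep_restr = prf1(test6.labels, restricted, old)

    f1_before = rep_before.per_class["f1"]
    f1_after = rep_after.per_class["f1"].loc[old]
    f1_restr = rep_restr.per_class["f1"]
    return pd.DataFrame({
        "f1_before": f1_before,
        "f1_after": f1_after,
        "f1_after_restricted": f1_restr,
        "delta": f1_after - f1_before,
        "delta_restricted": f1_restr - f1_before,
    })
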