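"""Metrics and cross-validation orchestration.

Per-class precision, recall and F1 are computed one-vs-rest from the
confusion matrix; the micro average pools TP/FP/FN over classes and, for
single-label multi-class prediction, equals plain accuracy.  Cross-validated
results are reported as the cross-fold mean with the standard error of the
mean (sample standard deviation across folds divided by sqrt(n_folds)).

:func:`run_loso` drives the three evaluation protocols over leave-one-
subject-out folds:

* ``pooled`` — train on the source subjects' trials 1-4 (validation trial
  5), evaluate on their held-out trial 6: the closed-set baseline.
* ``adapt`` — additionally score the unseen target subject before and after
  few-shot calibration on the target's trials 3-6.
* ``expand`` — train a base classifier on the subset of original classes,
  widen it to the full class list with weight transfer, run the two-phase
  protocol and report both phases plus a forgetting table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adapt import expand_classes, few_shot_finetune, forgetting_report, two_phase_train
from .classifier import (
    ClassifierConfig,
    build_classifier,
    predict,
    train_classifier,
)
from .csae import CSAEConfig, build_csae, train_csae
from .data import Recording, apply_scaler, fit_scaler, make_loso_folds, segment_cohort
from .nn import TrainConfig


@dataclass
class MetricsReport:
    """Per-class and micro-averaged classification metrics."""

    class_list: list[str]
    confusion: np.ndarray            # (K, K), rows true, cols predicted
    per_class: pd.DataFrame          # index class; precision/recall/f1/tp/fp/fn/support
    micro_f1: float
    n: int
    zero_division_classes: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.n)


def prf1(y_true, y_pred, class_list: list[str]) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus the micro average.

    Zero-division (a class never predicted, or absent from the truth)
    yields 0 for the affected ratio and flags the class.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    class_list = [str(c) for c in class_list]
    index = {c: i for i, c in enumerate(class_list)}
    unknown = (set(y_true) | set(y_pred)) - set(class_list)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class list")
    K = len(class_list)
    confusion = np.zeros((K, K), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        confusion[index[t], index[p]] += 1
    tp = np.diag(confusion).astype(float)
    fp = confusion.sum(axis=0) - tp
    fn = confusion.sum(axis=1) - tp
    flagged = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    for i, c in enumerate(class_list):
        if tp[i] + fp[i] == 0 or tp[i] + fn[i] == 0:
            flagged.append(c)
    micro_tp, micro_fp, micro_fn = tp.sum(), fp.sum(), fn.sum()
    micro_p = micro_tp / (micro_tp + micro_fp) if micro_tp + micro_fp else 0.0
    micro_r = micro_tp / (micro_tp + micro_fn) if micro_tp + micro_fn else 0.0
    micro_f1 = (2 * micro_p * micro_r / (micro_p + micro_r)
                if micro_p + micro_r else 0.0)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1,
         "tp": tp.astype(int), "fp": fp.astype(int), "fn": fn.astype(int),
         "support": confusion.sum(axis=1)},
        index=pd.Index(class_list, name="class"))
    return MetricsReport(class_list=class_list, confusion=confusion,
                         per_class=per_class, micro_f1=float(micro_f1),
                         n=len(y_true), zero_division_classes=flagged)


@dataclass
class CVReport:
    """Cross-validation summary: one MetricsReport per fold."""

    fold_reports: list[MetricsReport]
    fold_targets: list[str]

    @property
    def n_folds(self) -> int:
        return len(self.fold_reports)

    @property
    def micro_f1_by_fold(self) -> np.ndarray:
        return np.array([r.micro_f1 for r in self.fold_reports])

    @property
    def mean_micro_f1(self) -> float:
        return float(self.micro_f1_by_fold.mean())

    @property
    def se_micro_f1(self) -> float:
        """Standard error of the mean: std across folds / sqrt(n_folds)."""
        x = self.micro_f1_by_fold
        if len(x) < 2:
            return 0.0
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    def per_class_summary(self) -> pd.DataFrame:
        """Cross-fold mean and SE of per-class F1."""
        stacked = pd.concat([r.per_class["f1"] for r in self.fold_reports], axis=1)
        n = stacked.shape[1]
        se = stacked.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else 0.0 * stacked.iloc[:, 0]
        return pd.DataFrame({"f1_mean": stacked.mean(axis=1), "f1_se": se})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"target_subject": self.fold_targets,
                             "micro_f1": self.micro_f1_by_fold})


def confusion_flow(report: MetricsReport, class_a: str, class_b: str) -> float:
    """Fraction of class_a's misclassified instances predicted as class_b.

    Returns NaN when class_a has no misclassifications (undefined).
    """
    ia = report.class_list.index(str(class_a))
    ib = report.class_list.index(str(class_b))
    row = report.confusion[ia]
    errors = row.sum() - row[ia]
    if errors == 0:
        return float("nan")
    return float(row[ib] / errors)


def class_order(cohort: list[Recording]) -> list[str]:
    """Gesture ids in order of first appearance — the canonical class list."""
    seen: dict[str, None] = {}
    for r in cohort:
        seen.setdefault(str(r.gesture_id), None)
    return list(seen)


def _fold_seed(seed: int, fold_idx: int, salt: int = 0) -> int:
    """Deterministic per-fold seed derived from the global seed."""
    return int(np.random.default_rng([seed % (2**31), fold_idx, salt])
               .integers(2**31))


def _train_fold_models(train_s, val_s, classes, csae_config, clf_config,
                       tc_csae, tc_clf, fold_seed):
    """Scaler-standardized inputs -> trained (autoencoder, classifier)."""
    T, C = train_s.segments.shape[1:]
    ae = build_csae(replace(csae_config, seed=fold_seed), (T, C))
    train_csae(ae, train_s, val_s, tc_csae)
    ccfg = replace(clf_config, n_classes=len(classes), seed=fold_seed + 1)
    clf = build_classifier(ae, ccfg, classes)
    train_classifier(clf, train_s, val_s, tc_clf)
    return ae, clf


def run_loso(cohort: list[Recording], *, protocol: str = "pooled",
             csae_config: CSAEConfig | None = None,
             clf_config: ClassifierConfig | None = None,
             tc_csae: TrainConfig | None = None,
             tc_clf: TrainConfig | None = None,
             tc_calib: TrainConfig | None = None,
             tc_phase1: TrainConfig | None = None,
             tc_phase2: TrainConfig | None = None,
             base_classes: list[str] | None = None,
             window_ms: float = 250.0, stride_ms: float = 125.0,
             seed: int = 0, folds: list[int] | None = None):
    """Leave-one-subject-out evaluation under one of three protocols.

    Returns a :class:`CVReport` for ``pooled``; a dict of CVReports (and,
    for ``expand``, per-fold forgetting tables) otherwise.  ``folds``
    selects a subset of fold indices for reduced-scale runs.  Per-fold model
    seeds are derived deterministically from ``seed`` and the fold index.
    """
    if protocol not in ("pooled", "adapt", "expand"):
        raise ValueError(f"unknown protocol {protocol!r}")
    csae_config = csae_config or CSAEConfig()
    clf_config = clf_config or ClassifierConfig(n_classes=2)
    tc_csae = tc_csae or TrainConfig()
    tc_clf = tc_clf or TrainConfig()
    classes = class_order(cohort)
    batch = segment_cohort(cohort, window_ms, stride_ms)
    plans = make_loso_folds(cohort)
    indices = list(range(len(plans))) if folds is None else list(folds)

    pooled_reports, pre_reports, post_reports = [], [], []
    p1_reports, p2_reports, base6_reports, forgetting = [], [], [], []
    targets = []

    for fi in indices:
        plan = plans[fi]
        plan.assert_no_leakage()
        targets.append(plan.target_subject)
        fseed = _fold_seed(seed, fi)
        src = batch.select(subjects=plan.source_subjects)
        if protocol == "expand":
            if base_classes is None:
                base_classes = classes[:6]
            src_base = src.select(labels=base_classes)
            train = src_base.select(trials=plan.source_train_trials)
        else:
            train = src.select(trials=plan.source_train_trials)
        scaler = fit_scaler(train, fitted_on=f"source-train fold {fi}")

        def std(b):
            return apply_scaler(b, scaler)

        if protocol in ("pooled", "adapt"):
            train_s = std(train)
            val_s = std(src.select(trials=plan.source_val_trials))
            test_s = std(src.select(trials=plan.source_test_trials))
            ae, clf = _train_fold_models(train_s, val_s, classes, csae_config,
                                         clf_config, tc_csae, tc_clf, fseed)
            _, labels = predict(clf, test_s)
            pooled_reports.append(prf1(test_s.labels, labels, classes))

            if protocol == "adapt":
                tgt = batch.select(subjects=[plan.target_subject])
                tgt_test = std(tgt.select(trials=plan.target_test_trials))
                _, labels = predict(clf, tgt_test)
                pre_reports.append(prf1(tgt_test.labels, labels, classes))
                calib_s = std(tgt.select(trials=plan.target_calib_trials))
                tval_s = std(tgt.select(trials=plan.target_val_trials))
                few_shot_finetune(clf, calib_s, tval_s, tc_calib or tc_clf,
                                  rng=np.random.default_rng(fseed + 2))
                _, labels = predict(clf, tgt_test)
                post_reports.append(prf1(tgt_test.labels, labels, classes))

        else:  # expand
            src_base = src.select(labels=base_classes)
            train_s = std(train)
            val6_s = std(src_base.select(trials=plan.source_val_trials))
            test6_s = std(src_base.select(trials=plan.source_test_trials))
            ae, clf6 = _train_fold_models(train_s, val6_s, base_classes,
                                          csae_config, clf_config, tc_csae,
                                          tc_clf, fseed)
            _, labels = predict(clf6, test6_s)
            base6_reports.append(prf1(test6_s.labels, labels, base_classes))

            train10_s = std(src.select(trials=plan.source_train_trials))
            val10_s = std(src.select(trials=plan.source_val_trials))
            test10_s = std(src.select(trials=plan.source_test_trials))
            clf10 = expand_classes(clf6, classes, seed=fseed + 3)
            tc1 = tc_phase1 or tc_clf
            tc2 = tc_phase2 or replace(tc1, learning_rate=0.1 * tc1.learning_rate)
            clf10, info = two_phase_train(
                clf10, train10_s, val10_s, tc1, tc2, test=test10_s,
                rng=np.random.default_rng(fseed + 4))
            p1_reports.append(info["phase1_report"])
            p2_reports.append(info["phase2_report"])
            forgetting.append(forgetting_report(clf6, clf10, test6_s))

    if protocol == "pooled":
        return CVReport(pooled_reports, targets)
    if protocol == "adapt":
        return {"pooled": CVReport(pooled_reports, targets),
                "pre": CVReport(pre_reports, targets),
                "post": CVReport(post_reports, targets)}
    return {"base6": CVReport(base6_reports, targets),
            "phase1": CVReport(p1_reports, targets),
            "phase2": CVReport(p2_reports, targets),
            "forgetting": forgetting}


def lambda_sweep(cohort: list[Recording], lambdas, filter_grid, *,
                 csae_config: CSAEConfig | None = None,
                 clf_config: ClassifierConfig | None = None,
                 tc_csae: TrainConfig | None = None,
                 tc_clf: TrainConfig | None = None,
                 window_ms: float = 250.0, stride_ms: float = 125.0,
                 seed: int = 0, folds: list[int] | None = None,
                 near_zero_tol: float = 1e-3) -> tuple[pd.DataFrame, dict]:
    """Grid sweep over the L1 coefficient and bottleneck width.

    For every (lambda, D) pair a fresh autoencoder + classifier is trained
    per fold; the table reports cross-fold mean/SE micro-F1 plus two
    sparsity diagnostics of the bottleneck on the held-out test set: the
    mean absolute activation and the fraction of activations below
    ``near_zero_tol``.  Returns (table, best-row-as-dict by mean F1).
    """
    lambdas = list(lambdas)
    filter_grid = list(filter_grid)
    if not lambdas or not filter_grid:
        raise ValueError("grids must be non-empty")
    csae_config = csae_config or CSAEConfig()
    clf_config = clf_config or ClassifierConfig(n_classes=2)
    tc_csae = tc_csae or TrainConfig()
    tc_clf = tc_clf or TrainConfig()
    classes = class_order(cohort)
    batch = segment_cohort(cohort, window_ms, stride_ms)
    plans = make_loso_folds(cohort)
    indices = list(range(len(plans))) if folds is None else list(folds)

    rows = []
    for lam in lambdas:
        for D in filter_grid:
            f1s, zfracs, zabs = [], [], []
            for fi in indices:
                plan = plans[fi]
                fseed = _fold_seed(seed, fi, salt=hash((float(lam), int(D))) % 997)
                src = batch.select(subjects=plan.source_subjects)
                train = src.select(trials=plan.source_train_trials)
                scaler = fit_scaler(train)
                train_s = apply_scaler(train, scaler)
                val_s = apply_scaler(src.select(trials=plan.source_val_trials), scaler)
                test_s = apply_scaler(src.select(trials=plan.source_test_trials), scaler)
                cfg = replace(csae_config, l1_coeff=float(lam),
                              latent_filters=int(D))
                ae, clf = _train_fold_models(train_s, val_s, classes, cfg,
                                             clf_config, tc_csae, tc_clf, fseed)
                _, labels = predict(clf, test_s)
                f1s.append(prf1(test_s.labels, labels, classes).micro_f1)
                Z = ae.encode(test_s)
                zfracs.append(float((np.abs(Z) < near_zero_tol).mean()))
                zabs.append(float(np.abs(Z).mean()))
            n = len(f1s)
            rows.append({
                "lambda": float(lam), "latent_filters": int(D),
                "mean_f1": float(np.mean(f1s)),
                "se_f1": float(np.std(f1s, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "near_zero_frac": float(np.mean(zfracs)),
                "mean_abs_z": float(np.mean(zabs)),
            })
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_f1"].idxmax()].to_dict()
    return table, best
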