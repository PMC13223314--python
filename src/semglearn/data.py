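"""Domain types and leakage-safe data handling for multi-trial sEMG cohorts.

A *Recording* is one continuous multichannel trial for one (subject, gesture)
pair.  Recordings are cut into fixed-length overlapping windows (the unit of
classification), standardized per channel with statistics fitted on training
data only, and organised into leave-one-subject-out (LOSO) folds: in each
fold one subject is the completely unseen target, the remaining subjects form
the source domain with a chronological trial split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

#: Floor applied to a zero-variance channel before dividing.
SCALER_EPS = 1e-8

#: Source-domain trial split: train / validation / test.
DEFAULT_SOURCE_TRIALS = ((1, 2, 3, 4), (5,), (6,))
#: Target-subject trial split: calibration / validation / held-out test.
DEFAULT_TARGET_TRIALS = ((1,), (2,), (3, 4, 5, 6))


@dataclass
class Recording:
    """One continuous trial: L time samples x C channels at ``fs`` Hz."""

    subject_id: str
    gesture_id: str
    trial_id: int
    samples: np.ndarray  # (L, C), voltage in arbitrary units
    fs: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a non-empty (L, C) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs


@dataclass
class SegmentBatch:
    """N windows of shape (T, C) with per-window provenance."""

    segments: np.ndarray          # (N, T, C)
    labels: np.ndarray            # (N,) gesture ids (str)
    subject_ids: np.ndarray       # (N,)
    trial_ids: np.ndarray         # (N,) int
    window_ms: float
    stride_ms: float
    fs: float

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        n = len(self.segments)
        if not (len(self.labels) == len(self.subject_ids) == len(self.trial_ids) == n):
            raise ValueError("provenance arrays must match the number of segments")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments.shape[2]

    def select(self, subjects=None, trials=None, labels=None) -> "SegmentBatch":
        """Subset by subject ids, trial ids and/or gesture labels."""
        mask = np.ones(len(self), dtype=bool)
        if subjects is not None:
            mask &= np.isin(self.subject_ids.astype(str), [str(s) for s in subjects])
        if trials is not None:
            mask &= np.isin(self.trial_ids, list(trials))
        if labels is not None:
            mask &= np.isin(self.labels.astype(str), [str(g) for g in labels])
        return SegmentBatch(self.segments[mask], self.labels[mask],
                            self.subject_ids[mask], self.trial_ids[mask],
                            self.window_ms, self.stride_ms, self.fs)

    @staticmethod
    def concatenate(batches: list["SegmentBatch"]) -> "SegmentBatch":
        if not batches:
            raise ValueError("nothing to concatenate")
        b0 = batches[0]
        for b in batches[1:]:
            if (b.window_ms, b.stride_ms, b.fs) != (b0.window_ms, b0.stride_ms, b0.fs):
                raise ValueError("batches have inconsistent windowing parameters")
        return SegmentBatch(
            np.concatenate([b.segments for b in batches]),
            np.concatenate([b.labels for b in batches]),
            np.concatenate([b.subject_ids for b in batches]),
            np.concatenate([b.trial_ids for b in batches]),
            b0.window_ms, b0.stride_ms, b0.fs)

    # -- persistence -------------------------------------------------------

    def to_hdf5(self, path, group: str = "segments") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("segments", data=self.segments)
            g.create_dataset("labels", data=self.labels.astype("S"))
            g.create_dataset("subject_ids", data=self.subject_ids.astype("S"))
            g.create_dataset("trial_ids", data=self.trial_ids)
            g.attrs["window_ms"] = self.window_ms
            g.attrs["stride_ms"] = self.stride_ms
            g.attrs["fs"] = self.fs

    @staticmethod
    def from_hdf5(path, group: str = "segments") -> "SegmentBatch":
        with h5py.File(path, "r") as f:
            g = f[group]
            return SegmentBatch(
                g["segments"][:],
                g["labels"][:].astype(str),
                g["subject_ids"][:].astype(str),
                g["trial_ids"][:],
                float(g.attrs["window_ms"]), float(g.attrs["stride_ms"]),
                float(g.attrs["fs"]))


@dataclass
class ScalerStats:
    """Per-channel standardization statistics, fitted on training data only."""

    mean: np.ndarray      # (C,)
    std: np.ndarray       # (C,)
    fitted_on: str = "unspecified"

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=np.float64))
        if np.any(self.std <= 0):
            raise ValueError("std entries must be positive (epsilon-floored)")


@dataclass
class SplitPlan:
    """One LOSO fold: source subjects with a trial split, plus the held-out
    target subject with calibration/validation/test trials."""

    target_subject: str
    source_subjects: tuple[str, ...]
    source_train_trials: tuple[int, ...] = DEFAULT_SOURCE_TRIALS[0]
    source_val_trials: tuple[int, ...] = DEFAULT_SOURCE_TRIALS[1]
    source_test_trials: tuple[int, ...] = DEFAULT_SOURCE_TRIALS[2]
    target_calib_trials: tuple[int, ...] = DEFAULT_TARGET_TRIALS[0]
    target_val_trials: tuple[int, ...] = DEFAULT_TARGET_TRIALS[1]
    target_test_trials: tuple[int, ...] = DEFAULT_TARGET_TRIALS[2]

    def __post_init__(self):
        self.source_subjects = tuple(str(s) for s in self.source_subjects)
        self.target_subject = str(self.target_subject)
        if self.target_subject in self.source_subjects:
            raise ValueError("target subject must not appear among source subjects")
        for name, groups in (
            ("source", (self.source_train_trials, self.source_val_trials,
                        self.source_test_trials)),
            ("target", (self.target_calib_trials, self.target_val_trials,
                        self.target_test_trials)),
        ):
            flat = [t for g in groups for t in g]
            if len(flat) != len(set(flat)):
                raise ValueError(f"{name} trial lists overlap: {groups}")

    def assert_no_leakage(self) -> None:
        """Verify that no (subject, trial) used for scaler-fit/training can
        appear in any evaluation partition of this fold."""
        train = {(s, t) for s in self.source_subjects for t in self.source_train_trials}
        evals = {(s, t) for s in self.source_subjects
                 for t in self.source_val_trials + self.source_test_trials}
        evals |= {(self.target_subject, t)
                  for t in self.target_val_trials + self.target_test_trials}
        overlap = train & evals
        if overlap:
            raise ValueError(f"leakage: {sorted(overlap)} in both train and evaluation")
        if self.target_subject in self.source_subjects:
            raise ValueError("target subject leaked into source domain")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def segment(recording: Recording, window_ms: float, stride_ms: float) -> SegmentBatch:
    """Cut a recording into overlapping fixed-length windows.

    Window i covers samples [i*S, i*S + T) (0-based, half-open) where T and S
    are the window and stride in samples; an incomplete tail is dropped, so
    the number of windows is floor((L - T)/S) + 1.
    """
    if stride_ms <= 0:
        raise ValueError("stride must be positive")
    T = round(window_ms * recording.fs / 1000.0)
    S = round(stride_ms * recording.fs / 1000.0)
    if S < 1 or T < 1:
        raise ValueError("window and stride must be at least one sample long")
    L = recording.n_samples
    if T > L:
        raise ValueError(
            f"window of {T} samples exceeds recording length {L}")
    n = (L - T) // S + 1
    starts = np.arange(n) * S
    segs = np.stack([recording.samples[s : s + T] for s in starts])
    return SegmentBatch(
        segments=segs,
        labels=np.full(n, recording.gesture_id, dtype=object),
        subject_ids=np.full(n, recording.subject_id, dtype=object),
        trial_ids=np.full(n, recording.trial_id),
        window_ms=window_ms, stride_ms=stride_ms, fs=recording.fs)


def segment_cohort(cohort: list[Recording], window_ms: float,
                   stride_ms: float) -> SegmentBatch:
    """Segment every recording in a cohort into one batch."""
    if not cohort:
        raise ValueError("empty cohort")
    fs = {r.fs for r in cohort}
    ch = {r.n_channels for r in cohort}
    if len(fs) > 1 or len(ch) > 1:
        raise ValueError("all recordings in a cohort must share fs and channel count")
    return SegmentBatch.concatenate(
        [segment(r, window_ms, stride_ms) for r in cohort])


def fit_scaler(train: SegmentBatch, fitted_on: str = "train") -> ScalerStats:
    """Per-channel mean/std pooled over all time samples of all segments."""
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty batch")
    flat = train.segments.reshape(-1, train.n_channels)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    if np.any(std < SCALER_EPS):
        warnings.warn(
            "zero-variance channel(s) encountered; applying epsilon floor "
            f"{SCALER_EPS}", RuntimeWarning, stacklevel=2)
        std = np.maximum(std, SCALER_EPS)
    return ScalerStats(mean=mean, std=std, fitted_on=fitted_on)


def apply_scaler(batch: SegmentBatch, stats: ScalerStats) -> SegmentBatch:
    """Standardize: (x - mean_c) / std_c per channel."""
    if batch.n_channels != len(stats.mean):
        raise ValueError(
            f"channel mismatch: batch has {batch.n_channels}, "
            f"scaler was fitted on {len(stats.mean)}")
    segs = (batch.segments - stats.mean) / stats.std
    return replace(batch, segments=segs)


def make_loso_folds(cohort: list[Recording], **plan_overrides) -> list[SplitPlan]:
    """One SplitPlan per subject, each subject serving as target exactly once.

    ``plan_overrides`` replace the default trial assignments (source
    {1,2,3,4}/{5}/{6}; target {1}/{2}/{3,4,5,6}).
    """
    subjects = sorted({str(r.subject_id) for r in cohort})
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least two subjects")
    # verify every (subject, gesture) has the trials the plan needs
    probe = SplitPlan(target_subject=subjects[0],
                      source_subjects=tuple(subjects[1:]), **plan_overrides)
    needed = set(probe.source_train_trials + probe.source_val_trials +
                 probe.source_test_trials + probe.target_calib_trials +
                 probe.target_val_trials + probe.target_test_trials)
    have: dict[tuple[str, str], set[int]] = {}
    for r in cohort:
        have.setdefault((str(r.subject_id), str(r.gesture_id)), set()).add(r.trial_id)
    for (s, g), trials in sorted(have.items()):
        missing = needed - trials
        if missing:
            raise ValueError(
                f"subject {s}, gesture {g}: missing trials {sorted(missing)} "
                "required by the split plan")
    folds = []
    for target in subjects:
        plan = SplitPlan(
            target_subject=target,
            source_subjects=tuple(s for s in subjects if s != target),
            **plan_overrides)
        plan.assert_no_leakage()
        folds.append(plan)
    return folds


# ---------------------------------------------------------------------------
# Cohort I/O: one CSV per trial plus a manifest
# ---------------------------------------------------------------------------


def save_cohort_csv(cohort: list[Recording], out_dir) -> "pd.DataFrame":
    """Write one headerless CSV per trial (one column per channel) and a
    manifest with columns subject_id,gesture_id,trial_id,fs_hz,path."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in cohort:
        name = f"{r.subject_id}_{r.gesture_id}_t{r.trial_id}.csv"
        np.savetxt(out / name, r.samples, delimiter=",", fmt="%.6g")
        rows.append({"subject_id": r.subject_id, "gesture_id": r.gesture_id,
                     "trial_id": r.trial_id, "fs_hz": r.fs, "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_cohort_csv(manifest_path) -> list[Recording]:
    """Load a cohort from a manifest CSV (paths relative to the manifest).

    Per-trial lengths may differ; channel count and sampling rate must not.
    """
    from pathlib import Path

    mpath = Path(manifest_path)
    if mpath.is_dir():
        mpath = mpath / "manifest.csv"
    manifest = pd.read_csv(mpath)
    required = {"subject_id", "gesture_id", "trial_id", "fs_hz", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest missing columns {required - set(manifest.columns)}")
    cohort = []
    for _, row in manifest.iterrows():
        samples = np.loadtxt(mpath.parent / row["path"], delimiter=",", ndmin=2)
        cohort.append(Recording(str(row["subject_id"]), str(row["gesture_id"]),
                                int(row["trial_id"]), samples, float(row["fs_hz"])))
    return cohort


def one_hot(labels: np.ndarray, class_list: list[str]) -> np.ndarray:
    """Deterministic one-hot encoding in class-list order."""
    index = {str(c): i for i, c in enumerate(class_list)}
    try:
        idx = np.array([index[str(label)] for label in labels])
    except KeyError as e:
        raise ValueError(f"label {e} not in class list {class_list}") from None
    out = np.zeros((len(labels), len(class_list)))
    out[np.arange(len(labels)), idx] = 1.0
    return out
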