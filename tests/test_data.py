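"""Segmentation, standardization and LOSO split construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semglearn.data import (
    Recording,
    ScalerStats,
    SegmentBatch,
    SplitPlan,
    apply_scaler,
    fit_scaler,
    load_cohort_csv,
    make_loso_folds,
    one_hot,
    save_cohort_csv,
    segment,
)


def _recording(L, C=2, fs=4000.0, subject="S1", gesture="g", trial=1, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(subject, gesture, trial, rng.normal(size=(L, C)), fs)


class TestSegment:
    def test_five_second_trial_at_4khz_yields_39_windows(self):
        batch = segment(_recording(20000), 250.0, 125.0)
        assert len(batch) == 39  # floor((20000-1000)/500)+1
        assert batch.segments.shape == (39, 1000, 2)

    def test_exact_single_window(self):
        rec = _recording(1000)
        batch = segment(rec, 250.0, 125.0)
        assert len(batch) == 1
        np.testing.assert_array_equal(batch.segments[0], rec.samples)

    def test_window_length_is_1000_samples_at_4khz(self):
        batch = segment(_recording(5000), 250.0, 125.0)
        assert batch.segments.shape[1] == 1000

    def test_windows_start_at_multiples_of_stride(self):
        rec = _recording(3000)
        batch = segment(rec, 250.0, 125.0)
        for i in range(len(batch)):
            np.testing.assert_array_equal(batch.segments[i],
                                          rec.samples[i * 500 : i * 500 + 1000])

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment(_recording(800), 250.0, 125.0)

    def test_nonpositive_stride_rejected(self):
        with pytest.raises(ValueError, match="stride"):
            segment(_recording(2000), 250.0, 0.0)

    @settings(max_examples=60, deadline=None)
    @given(L=st.integers(10, 3000), T=st.integers(2, 400), S=st.integers(1, 300))
    def test_count_matches_closed_form_and_no_overrun(self, L, T, S):
        if T > L:
            return
        fs = 1000.0  # 1 sample per ms keeps durations integral
        batch = segment(_recording(L, fs=fs), float(T), float(S))
        assert len(batch) == (L - T) // S + 1
        # last window must end inside the recording
        assert (len(batch) - 1) * S + T <= L


class TestScaler:
    def test_all_zero_train_floors_std_and_warns(self):
        batch = segment(_recording(2000), 250.0, 125.0)
        batch.segments[:] = 0.0
        with pytest.warns(RuntimeWarning, match="epsilon"):
            stats = fit_scaler(batch)
        np.testing.assert_array_equal(stats.mean, [0.0, 0.0])
        np.testing.assert_array_equal(stats.std, [1e-8, 1e-8])

    def test_symmetric_two_point_channel(self):
        batch = segment(_recording(2000), 250.0, 125.0)
        batch.segments[:] = 1.0
        batch.segments[:, ::2, :] = -1.0
        stats = fit_scaler(batch)
        np.testing.assert_allclose(stats.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.std, 1.0)

    def test_stats_equal_whole_batch_recomputation(self, rng):
        segs = rng.normal(2.0, 3.0, size=(17, 50, 2))
        batch = SegmentBatch(segs, ["g"] * 17, ["S1"] * 17, [1] * 17,
                             50.0, 25.0, 1000.0)
        stats = fit_scaler(batch)
        flat = segs.reshape(-1, 2)
        np.testing.assert_allclose(stats.mean, flat.mean(axis=0))
        np.testing.assert_allclose(stats.std, flat.std(axis=0))

    def test_transform_of_fit_partition_is_standardized(self, rng):
        segs = rng.normal(5.0, 0.3, size=(20, 40, 2))
        batch = SegmentBatch(segs, ["g"] * 20, ["S1"] * 20, [1] * 20,
                             40.0, 20.0, 1000.0)
        stats = fit_scaler(batch)
        out = apply_scaler(batch, stats)
        flat = out.segments.reshape(-1, 2)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-9)

    def test_constant_transform_arithmetic(self):
        segs = np.full((3, 10, 1), 4.0)
        batch = SegmentBatch(segs, ["g"] * 3, ["S1"] * 3, [1] * 3,
                             10.0, 5.0, 1000.0)
        out = apply_scaler(batch, ScalerStats(mean=[2.0], std=[2.0]))
        np.testing.assert_array_equal(out.segments, np.ones_like(segs))

    def test_same_distribution_test_batch_standardizes(self, rng):
        train = SegmentBatch(rng.normal(1.0, 2.0, size=(200, 30, 2)),
                             ["g"] * 200, ["S1"] * 200, [1] * 200,
                             30.0, 15.0, 1000.0)
        test = SegmentBatch(rng.normal(1.0, 2.0, size=(200, 30, 2)),
                            ["g"] * 200, ["S1"] * 200, [2] * 200,
                            30.0, 15.0, 1000.0)
        stats = fit_scaler(train)
        out = apply_scaler(test, stats)
        assert np.abs(out.segments.mean()) < 0.05  # sampling error only

    def test_channel_mismatch_rejected(self):
        batch = segment(_recording(2000, C=2), 250.0, 125.0)
        with pytest.raises(ValueError, match="channel mismatch"):
            apply_scaler(batch, ScalerStats(mean=[0.0], std=[1.0]))


def _cohort(n_subjects, n_trials=6, gestures=("a", "b")):
    return [
        _recording(400, fs=1000.0, subject=f"S{s}", gesture=g, trial=t,
                   seed=s * 100 + t)
        for s in range(1, n_subjects + 1)
        for g in gestures
        for t in range(1, n_trials + 1)
    ]


class TestLosoFolds:
    def test_eight_subjects_give_eight_folds_each_target_once(self):
        folds = make_loso_folds(_cohort(8))
        assert len(folds) == 8
        assert sorted(f.target_subject for f in folds) == [f"S{i}" for i in range(1, 9)]

    def test_two_subject_cohort(self):
        folds = make_loso_folds(_cohort(2))
        assert len(folds) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="two subjects"):
            make_loso_folds(_cohort(1))

    def test_missing_trial_error_names_the_gap(self):
        cohort = _cohort(3)
        cohort = [r for r in cohort
                  if not (r.subject_id == "S2" and r.trial_id == 5)]
        with pytest.raises(ValueError, match=r"S2.*\[5\]"):
            make_loso_folds(cohort)

    def test_source_and_target_partition_all_subjects(self):
        folds = make_loso_folds(_cohort(5))
        all_subjects = {f"S{i}" for i in range(1, 6)}
        for fold in folds:
            assert set(fold.source_subjects) | {fold.target_subject} == all_subjects
            assert fold.target_subject not in fold.source_subjects

    def test_default_trial_assignments(self):
        fold = make_loso_folds(_cohort(2))[0]
        assert fold.source_train_trials == (1, 2, 3, 4)
        assert fold.source_val_trials == (5,)
        assert fold.source_test_trials == (6,)
        assert fold.target_calib_trials == (1,)
        assert fold.target_val_trials == (2,)
        assert fold.target_test_trials == (3, 4, 5, 6)

    def test_leakage_guard_rejects_overlapping_trials(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(target_subject="S1", source_subjects=("S2",),
                      source_train_trials=(1, 2, 3, 4),
                      source_test_trials=(4,))

    def test_leakage_guard_rejects_target_in_sources(self):
        with pytest.raises(ValueError, match="target subject"):
            SplitPlan(target_subject="S1", source_subjects=("S1", "S2"))


class TestIO:
    def test_cohort_csv_roundtrip(self, tmp_path):
        cohort = _cohort(2, n_trials=6)
        save_cohort_csv(cohort, tmp_path)
        loaded = load_cohort_csv(tmp_path)
        assert len(loaded) == len(cohort)
        by_key = {(r.subject_id, r.gesture_id, r.trial_id): r for r in loaded}
        for r in cohort:
            other = by_key[(r.subject_id, r.gesture_id, r.trial_id)]
            np.testing.assert_allclose(other.samples, r.samples, rtol=1e-4)
            assert other.fs == r.fs

    def test_loader_tolerates_unequal_trial_lengths(self, tmp_path):
        cohort = _cohort(2)
        cohort[0] = _recording(350, fs=1000.0, subject="S1", gesture="a", trial=1)
        save_cohort_csv(cohort, tmp_path)
        loaded = load_cohort_csv(tmp_path)
        lengths = {r.n_samples for r in loaded}
        assert lengths == {350, 400}

    def test_segment_batch_hdf5_roundtrip(self, tmp_path):
        batch = segment(_recording(3000), 250.0, 125.0)
        path = tmp_path / "seg.h5"
        batch.to_hdf5(path)
        loaded = SegmentBatch.from_hdf5(path)
        np.testing.assert_array_equal(loaded.segments, batch.segments)
        assert list(loaded.labels) == list(batch.labels)
        assert loaded.window_ms == 250.0 and loaded.fs == 4000.0


class TestOneHot:
    def test_encoding_follows_class_order(self):
        y = one_hot(np.array(["b", "a", "b"]), ["a", "b"])
        np.testing.assert_array_equal(y, [[0, 1], [1, 0], [0, 1]])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not in class list"):
            one_hot(np.array(["c"]), ["a", "b"])
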