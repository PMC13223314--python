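"""Classifier head: architecture contracts, attention pooling, training."""

import numpy as np
import pytest

from semglearn.classifier import (
    ClassifierConfig,
    build_classifier,
    cross_entropy,
    attention_pool,
    load_classifier,
    predict,
    save_classifier,
    small_classifier_config,
    train_classifier,
)
from semglearn.data import ScalerStats
from semglearn.nn import AttentionPool, Tensor, TrainConfig

CLASSES6 = ["hand_close", "thumb", "index", "middle", "ring", "little"]


@pytest.fixture(scope="module")
def built_clf(trained_ae):
    return build_classifier(trained_ae, small_classifier_config(6, seed=3),
                            CLASSES6)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.eye(4)[[0, 1, 2]]
        assert cross_entropy(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_over_six_classes_is_ln6(self):
        p = np.full((5, 6), 1 / 6)
        y = np.eye(6)[[0, 1, 2, 3, 4]]
        assert cross_entropy(p, y) == pytest.approx(np.log(6), abs=1e-12)

    def test_uniform_over_ten_classes_is_ln10(self):
        p = np.full((3, 10), 0.1)
        y = np.eye(10)[[0, 5, 9]]
        assert cross_entropy(p, y) == pytest.approx(np.log(10), abs=1e-12)

    def test_zero_probability_is_clamped(self):
        p = np.array([[1.0, 0.0]])
        y = np.array([[0.0, 1.0]])
        value = cross_entropy(p, y)
        assert np.isfinite(value) and value == pytest.approx(-np.log(1e-12))


class TestAttentionPool:
    def test_equal_scores_give_time_mean(self, rng):
        attn = AttentionPool(4, 3, rng)
        attn.w.data[:] = 0.0  # scores identical for every timestep
        attn.b.data[:] = 0.0
        h = rng.normal(size=(6, 4))
        ctx, weights = attention_pool(h, attn)
        np.testing.assert_allclose(ctx, h.mean(axis=0))
        np.testing.assert_allclose(weights, np.full(6, 1 / 6))

    def test_dominant_score_selects_that_timestep(self, rng):
        attn = AttentionPool(2, 2, rng)
        h = rng.normal(size=(5, 2))
        scores = attn.scores(Tensor(h[None])).data[0, :, 0]
        # push one timestep's score far above the rest by hand
        boosted = scores.copy()
        boosted[3] += 50.0
        a = np.exp(boosted - boosted.max())
        a /= a.sum()
        ctx = (a[:, None] * h).sum(axis=0)
        np.testing.assert_allclose(ctx, h[3], atol=1e-15)

    def test_weights_are_a_distribution(self, rng):
        attn = AttentionPool(3, 2, rng)
        _, weights = attention_pool(rng.normal(size=(4, 7, 3)), attn)
        assert weights.shape == (4, 7)
        assert (weights >= 0).all()
        np.testing.assert_allclose(weights.sum(axis=1), 1.0)


class TestBuildAndPredict:
    def test_predictions_are_row_stochastic(self, built_clf, tiny_fold):
        probs, labels = predict(built_clf, tiny_fold["test"])
        assert probs.shape == (len(tiny_fold["test"]), 6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()
        assert set(labels) <= set(CLASSES6)

    def test_repeat_prediction_is_deterministic(self, built_clf, tiny_fold):
        p1, _ = predict(built_clf, tiny_fold["test"])
        p2, _ = predict(built_clf, tiny_fold["test"])
        np.testing.assert_array_equal(p1, p2)

    def test_same_seed_builds_identical_heads(self, trained_ae):
        c1 = build_classifier(trained_ae, small_classifier_config(6, seed=5), CLASSES6)
        c2 = build_classifier(trained_ae, small_classifier_config(6, seed=5), CLASSES6)
        assert c1.digest() == c2.digest()

    def test_argmax_ties_break_to_lowest_class_index(self, built_clf, tiny_fold):
        built = build_classifier(built_clf.encoder,
                                 small_classifier_config(6, seed=1), CLASSES6)
        built.out.w.data[:] = 0.0
        built.out.b.data[:] = 0.0  # all logits equal -> full tie
        _, labels = predict(built, tiny_fold["test"].segments[:5])
        assert all(label == CLASSES6[0] for label in labels)

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            ClassifierConfig(n_classes=1)

    def test_single_stage_mlp_rejected(self):
        with pytest.raises(ValueError, match="two stages"):
            ClassifierConfig(n_classes=3, mlp_dims=(32,))

    def test_manual_forward_oracle_single_sample(self, trained_ae):
        """Hand-rolled numpy replication of the full head on one sample."""
        clf = build_classifier(trained_ae, small_classifier_config(6, seed=8),
                               CLASSES6)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 250, 2))
        z = clf.encoder.encode(x)[0]  # (T', D)

        def lrelu(v):
            return np.where(v > 0, v, 0.01 * v)

        mu = z.mean(axis=1, keepdims=True)
        var = z.var(axis=1, keepdims=True)
        h = (z - mu) / np.sqrt(var + 1e-5) * clf.layer_norm.gamma.data \
            + clf.layer_norm.beta.data
        # stride-1 same-padded conv, kernel 3
        w, b = clf.conv.w.data, clf.conv.b.data
        padded = np.vstack([np.zeros((1, h.shape[1])), h, np.zeros((1, h.shape[1]))])
        conv = np.stack([
            (padded[t : t + 3, :, None] * w).sum(axis=(0, 1)) + b
            for t in range(h.shape[0])])
        conv = lrelu(conv)
        e = np.tanh(conv @ clf.attention.w.data + clf.attention.b.data) \
            @ clf.attention.v.data
        a = np.exp(e - e.max())
        a /= a.sum()
        ctx = (a * conv).sum(axis=0)
        m = lrelu(ctx @ clf.fc1.w.data + clf.fc1.b.data)
        m = lrelu(m @ clf.fc2.w.data + clf.fc2.b.data)
        logits = m @ clf.out.w.data + clf.out.b.data
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        probs, _ = predict(clf, x)
        np.testing.assert_allclose(probs[0], expected, atol=1e-10)


class TestTraining:
    def test_encoder_digest_unchanged_by_training(self, trained_ae, tiny_fold):
        clf = build_classifier(trained_ae, small_classifier_config(6, seed=2),
                               CLASSES6)
        enc_before = clf.group_digests()["encoder"]
        tc = TrainConfig(max_epochs=2, early_stop_patience=2, learning_rate=1e-3)
        train_classifier(clf, tiny_fold["train"], tiny_fold["val"], tc)
        assert clf.group_digests()["encoder"] == enc_before

    def test_single_class_training_rejected(self, built_clf, tiny_fold):
        single = tiny_fold["train"].select(labels=["thumb"])
        with pytest.raises(ValueError, match="distinct classes"):
            train_classifier(built_clf, single, tiny_fold["val"],
                             TrainConfig(max_epochs=1))

    def test_unknown_label_rejected(self, built_clf, tiny_fold):
        bad = tiny_fold["train"]
        bad = type(bad)(bad.segments[:4], ["nope"] * 4, bad.subject_ids[:4],
                        bad.trial_ids[:4], bad.window_ms, bad.stride_ms, bad.fs)
        with pytest.raises(ValueError, match="not in class list"):
            train_classifier(built_clf, bad, tiny_fold["val"],
                             TrainConfig(max_epochs=1))


class TestLabelOrderEquivariance:
    def test_permuting_class_list_permutes_probability_columns(self, built_clf,
                                                               tiny_fold):
        import copy

        perm = [3, 1, 5, 0, 2, 4]
        permuted = copy.deepcopy(built_clf)
        permuted.class_list = [built_clf.class_list[j] for j in perm]
        permuted.out.w.data = built_clf.out.w.data[:, perm]
        permuted.out.b.data = built_clf.out.b.data[perm]
        x = tiny_fold["test"].segments[:8]
        p0, l0 = predict(built_clf, x)
        p1, l1 = predict(permuted, x)
        np.testing.assert_allclose(p1, p0[:, perm], atol=1e-12)
        assert list(l0) == list(l1)


class TestCheckpoint:
    def test_classifier_roundtrip(self, built_clf, tmp_path, tiny_fold):
        path = tmp_path / "clf.h5"
        scaler = ScalerStats([0.0, 0.0], [1.0, 1.0], "unit")
        save_classifier(path, built_clf, scaler)
        loaded, loaded_scaler = load_classifier(path)
        assert loaded.class_list == built_clf.class_list
        p0, _ = predict(built_clf, tiny_fold["test"].segments[:4])
        p1, _ = predict(loaded, tiny_fold["test"].segments[:4])
        np.testing.assert_array_equal(p0, p1)
        assert loaded_scaler.fitted_on == "unit"
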