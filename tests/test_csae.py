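"""Autoencoder losses, architecture contracts and training behaviour."""

import numpy as np
import pytest

from semglearn.csae import (
    AutoencoderModel,
    CSAEConfig,
    build_csae,
    csae_loss,
    leaky_relu,
    load_csae,
    r2_reconstruction,
    save_csae,
    small_csae_config,
    sparsity_penalty,
    train_csae,
)
from semglearn.data import ScalerStats, SegmentBatch
from semglearn.nn import Tensor, TrainConfig


class TestLeakyRelu:
    def test_positive_branch_identity(self):
        assert leaky_relu(2.0, 0.3) == 2.0

    def test_negative_branch_scales(self):
        assert leaky_relu(-2.0, 0.1) == pytest.approx(-0.2)

    def test_zero_slope_coincides_with_relu(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_array_equal(leaky_relu(x, 0.0), np.maximum(x, 0.0))

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            leaky_relu(1.0, -0.1)


class TestSparsityPenalty:
    def test_zero_activations(self):
        assert sparsity_penalty(np.zeros((4, 5)), 0.5) == 0.0

    def test_direct_absolute_sum(self):
        assert sparsity_penalty(np.array([1.0, -2.0, 3.0]), 0.1) == pytest.approx(0.6)

    def test_disabled_penalty(self, rng):
        assert sparsity_penalty(rng.normal(size=(3, 4, 5)), 0.0) == 0.0

    def test_batch_convention_averages_over_samples(self, rng):
        """For a (N, T', D) batch the penalty is the per-sample |Z| sum
        averaged over N, keeping lambda batch-size invariant."""
        z = rng.normal(size=(6, 4, 3))
        expected = 0.2 * np.abs(z).sum() / 6
        assert sparsity_penalty(z, 0.2) == pytest.approx(expected)
        doubled = np.concatenate([z, z])
        assert sparsity_penalty(doubled, 0.2) == pytest.approx(expected)


class TestCsaeLoss:
    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=(3, 8, 2))
        assert csae_loss(x, x, np.zeros((3, 4, 1)), 0.0) == 0.0

    def test_unit_offset_gives_unit_mse(self, rng):
        x = rng.normal(size=(3, 8, 2))
        assert csae_loss(x, x + 1.0, np.zeros((3, 4, 1)), 0.0) == pytest.approx(1.0)

    def test_matches_hand_computation(self, rng):
        x = rng.normal(size=(4, 6, 2))
        xh = rng.normal(size=(4, 6, 2))
        z = rng.normal(size=(4, 3, 2))
        lam = 0.01
        expected = ((x - xh) ** 2).sum() / x.size + lam * np.abs(z).sum() / 4
        assert csae_loss(x, xh, z, lam) == pytest.approx(expected, rel=1e-12)

    def test_decomposes_into_mse_plus_penalty(self, rng):
        x = rng.normal(size=(4, 6, 2))
        xh = rng.normal(size=(4, 6, 2))
        z = rng.normal(size=(4, 3, 2))
        assert csae_loss(x, xh, z, 0.3) == csae_loss(x, xh, z, 0.0) \
            + sparsity_penalty(z, 0.3)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            csae_loss(np.zeros((2, 4, 1)), np.zeros((2, 5, 1)), np.zeros(1), 0.0)


class TestArchitecture:
    def test_latent_shape_follows_stride_product(self, rng):
        model = build_csae(small_csae_config(seed=0), (250, 2))
        z = model.encode(rng.normal(size=(3, 250, 2)))
        assert z.shape == (3, 250 // 10, 16)
        assert z.shape[1] < 250  # T' < T

    def test_reconstruction_restores_input_shape(self, rng):
        for strides in [(2, 2), (4, 5), (5, 2)]:
            cfg = CSAEConfig(enc_filters=(3, 4), enc_kernels=(5, 3, 3),
                             enc_strides=strides, latent_filters=2, seed=0)
            T = 20 * strides[0] * strides[1]
            model = build_csae(cfg, (T, 2))
            x = rng.normal(size=(2, T, 2))
            assert model.reconstruct(x).shape == x.shape

    def test_indivisible_length_rejected_at_build_time(self):
        with pytest.raises(ValueError, match="divisible"):
            build_csae(CSAEConfig(enc_strides=(4, 5)), (1002, 2))

    def test_same_seed_gives_identical_initialization(self):
        m1 = build_csae(small_csae_config(seed=9), (250, 2))
        m2 = build_csae(small_csae_config(seed=9), (250, 2))
        assert m1.digest() == m2.digest()

    def test_unit_strides_rejected(self):
        with pytest.raises(ValueError, match="strides"):
            CSAEConfig(enc_strides=(1, 5))

    def test_encode_is_deterministic(self, rng):
        model = build_csae(small_csae_config(seed=0), (250, 2))
        x = rng.normal(size=(2, 250, 2))
        np.testing.assert_array_equal(model.encode(x), model.encode(x))

    def test_encoder_matches_naive_convolution_oracle(self, rng):
        """Single-block toy encoder against an explicit loop convolution."""
        cfg = CSAEConfig(enc_filters=(1, 1), enc_kernels=(3, 3, 1),
                         enc_strides=(2, 2), latent_filters=1,
                         leaky_slope=0.1, seed=4)
        model = build_csae(cfg, (8, 1))
        x = rng.normal(size=(1, 8, 1))

        def naive_conv(signal, w, b, stride):
            K = w.shape[0]
            T = len(signal)
            T_out = -(-T // stride)
            pad_total = max((T_out - 1) * stride + K - T, 0)
            padded = np.concatenate([np.zeros((pad_total // 2, signal.shape[1])),
                                     signal,
                                     np.zeros((pad_total - pad_total // 2,
                                               signal.shape[1]))])
            out = np.zeros((T_out, w.shape[2]))
            for t in range(T_out):
                window = padded[t * stride : t * stride + K]
                for f in range(w.shape[2]):
                    out[t, f] = (window * w[:, :, f]).sum() + b[f]
            return out

        def lrelu(v):
            return np.where(v > 0, v, 0.1 * v)

        h = lrelu(naive_conv(x[0], model.enc1.w.data, model.enc1.b.data, 2))
        h = lrelu(naive_conv(h, model.enc2.w.data, model.enc2.b.data, 2))
        z_ref = lrelu(naive_conv(h, model.bottleneck.w.data,
                                 model.bottleneck.b.data, 1))
        np.testing.assert_allclose(model.encode(x)[0], z_ref, atol=1e-12)


class TestR2:
    def _identity_like_model(self):
        """Model whose reconstruct() is replaced for metric testing."""
        return build_csae(small_csae_config(seed=0), (250, 2))

    def test_perfect_reconstruction_scores_one(self, rng, monkeypatch):
        model = self._identity_like_model()
        x = rng.normal(size=(3, 250, 2))
        monkeypatch.setattr(AutoencoderModel, "reconstruct",
                            lambda self, b, chunk=512: np.asarray(b))
        assert r2_reconstruction(model, x) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng, monkeypatch):
        model = self._identity_like_model()
        x = rng.normal(size=(3, 250, 2))
        monkeypatch.setattr(AutoencoderModel, "reconstruct",
                            lambda self, b, chunk=512: np.full_like(
                                np.asarray(b), np.asarray(b).mean()))
        assert r2_reconstruction(model, x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        model = self._identity_like_model()
        x = rng.normal(size=(3, 250, 2))
        xh = model.reconstruct(x)
        expected = 1.0 - ((x - xh) ** 2).sum() / ((x - x.mean()) ** 2).sum()
        assert r2_reconstruction(model, x) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_batch_rejected(self):
        model = self._identity_like_model()
        with pytest.raises(ValueError, match="zero-variance"):
            r2_reconstruction(model, np.zeros((2, 250, 2)))


def _const_batch(value, n=32, T=20, C=1, trial=1):
    rng = np.random.default_rng(0)
    segs = np.full((n, T, C), value) + 0.01 * rng.normal(size=(n, T, C))
    return SegmentBatch(segs, ["g"] * n, ["S1"] * n, [trial] * n, 20.0, 10.0, 1000.0)


class TestTraining:
    def test_constant_signal_is_learnable(self):
        """A near-constant dataset drives validation MSE to ~0 at lambda=0."""
        cfg = CSAEConfig(enc_filters=(2, 2), enc_kernels=(3, 3, 3),
                         enc_strides=(2, 2), latent_filters=2, l1_coeff=0.0,
                         seed=0)
        model = build_csae(cfg, (20, 1))
        tc = TrainConfig(max_epochs=60, early_stop_patience=60, batch_size=8,
                         learning_rate=5e-3)
        train_csae(model, _const_batch(0.5, trial=1), _const_batch(0.5, trial=2), tc)
        assert model.history["val_loss"][-1] < 0.01

    def test_history_records_epochs_and_losses(self, trained_ae):
        h = trained_ae.history
        assert h["stopped_epoch"] >= 1
        assert len(h["val_loss"]) == h["stopped_epoch"]
        assert all(np.isfinite(v) for v in h["val_loss"])


class TestCheckpoint:
    def test_roundtrip_preserves_model_and_scaler(self, trained_ae, tmp_path, rng):
        scaler = ScalerStats(mean=[0.1, -0.2], std=[1.5, 2.0], fitted_on="test")
        path = tmp_path / "model.h5"
        save_csae(path, trained_ae, scaler)
        loaded, loaded_scaler = load_csae(path)
        assert loaded.digest() == trained_ae.digest()
        assert loaded.config == trained_ae.config
        x = rng.normal(size=(2, 250, 2))
        np.testing.assert_array_equal(loaded.encode(x), trained_ae.encode(x))
        np.testing.assert_array_equal(loaded_scaler.mean, scaler.mean)

    def test_wrong_kind_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "other.h5"
        with h5py.File(path, "w") as f:
            f.attrs["kind"] = "something"
        with pytest.raises(ValueError, match="not a CSAE"):
            load_csae(path)
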