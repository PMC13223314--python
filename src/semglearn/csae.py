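"""Convolutional sparse autoencoder (CSAE) for raw sEMG segments.

The encoder f_phi compresses a standardized (T, C) segment through two
strided 1-D convolutional blocks into a bottleneck feature map
Z in R^{T' x D} (T' < T); the decoder g_theta mirrors the encoder with
transposed convolutions of the same strides and reconstructs the segment.
Strided convolutions replace pooling so that downsampling itself is
learnable; every layer uses a LeakyReLU activation.

Training minimizes a composite loss: the elementwise mean squared
reconstruction error plus an L1 activity penalty on the bottleneck
activations,

    L = MSE(X, X_hat) + lambda * sum|Z| / N,

i.e. the penalty sums |Z| over all activations of a sample and averages
over the batch, keeping lambda's meaning batch-size invariant.  The L1 term
is applied post-activation, penalizing the representation the encoder
actually emits.  Optimization is AdamW with He-Normal initialization,
plateau learning-rate decay, early stopping and best-validation restore.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .data import ScalerStats, SegmentBatch
from .nn import (
    Conv1d,
    ConvTranspose1d,
    Module,
    Tensor,
    TrainConfig,
    fit,
)

CHECKPOINT_SCHEMA = 1


def leaky_relu(x, alpha: float):
    """LeakyReLU: x if x > 0 else alpha * x, elementwise (numpy in/out)."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    x = np.asarray(x)
    return np.where(x > 0, x, alpha * x)


def sparsity_penalty(Z, lam: float) -> float:
    """L1 activity penalty: lambda * sum_i |Z_i|, averaged over the batch.

    A 3-D ``Z`` is treated as (N, T', D) and the absolute sum is averaged
    over the leading batch axis; lower-dimensional input is a single sample.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Z = np.asarray(Z)
    n = Z.shape[0] if Z.ndim == 3 else 1
    return float(lam * np.abs(Z).sum() / n)


def csae_loss(X, X_hat, Z, lam: float) -> float:
    """Composite loss: elementwise-mean squared error + sparsity penalty."""
    X, X_hat = np.asarray(X), np.asarray(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    mse = float(np.mean((X - X_hat) ** 2))
    return mse + sparsity_penalty(Z, lam)


@dataclass
class CSAEConfig:
    """Architecture hyperparameters.

    Defaults give T' = T/20 with a 32-filter bottleneck: Conv I 32 filters
    kernel 7 stride 4, Conv II 64 filters kernel 5 stride 5, bottleneck
    kernel 3 stride 1.  ``l1_coeff`` defaults to 1e-7, the sparsity level
    at which downstream classification peaks.
    """

    enc_filters: tuple[int, int] = (32, 64)
    enc_kernels: tuple[int, int, int] = (7, 5, 3)
    enc_strides: tuple[int, int] = (4, 5)
    latent_filters: int = 32
    leaky_slope: float = 0.01
    l1_coeff: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if len(self.enc_filters) != 2 or len(self.enc_strides) != 2 \
                or len(self.enc_kernels) != 3:
            raise ValueError("expected 2 filter counts, 2 strides, 3 kernels")
        if min(self.enc_strides) <= 1:
            raise ValueError("encoder strides must be > 1 (learnable downsampling)")
        if self.latent_filters < 1:
            raise ValueError("need at least one latent filter")
        if self.l1_coeff < 0 or self.leaky_slope < 0:
            raise ValueError("l1_coeff and leaky_slope must be nonnegative")

    @property
    def stride_product(self) -> int:
        return int(np.prod(self.enc_strides))


def small_csae_config(**overrides) -> CSAEConfig:
    """A compact configuration for desk-scale experiments (T' = T/10)."""
    defaults = dict(enc_filters=(16, 32), enc_kernels=(7, 5, 3),
                    enc_strides=(5, 2), latent_filters=16)
    defaults.update(overrides)
    return CSAEConfig(**defaults)


class AutoencoderModel(Module):
    """Symmetric strided-conv encoder / transposed-conv decoder pair."""

    def __init__(self, config: CSAEConfig, input_shape: tuple[int, int]):
        super().__init__()
        T, C = input_shape
        if T % config.stride_product != 0:
            raise ValueError(
                f"segment length {T} is not divisible by the stride product "
                f"{config.stride_product}; shapes would not reconstruct")
        self.config = config
        self.input_shape = (T, C)
        self.latent_length = T // config.stride_product
        f1, f2 = config.enc_filters
        k1, k2, k3 = config.enc_kernels
        s1, s2 = config.enc_strides
        rng = np.random.default_rng(config.seed % (2**31))
        # encoder: Conv I, Conv II, bottleneck Conv III
        self.enc1 = Conv1d(C, f1, k1, s1, rng)
        self.enc2 = Conv1d(f1, f2, k2, s2, rng)
        self.bottleneck = Conv1d(f2, config.latent_filters, k3, 1, rng)
        # decoder: mirrored strides in transposed order + linear output conv
        self.dec1 = ConvTranspose1d(config.latent_filters, f2, k2, s2, rng)
        self.dec2 = ConvTranspose1d(f2, f1, k1, s1, rng)
        self.out = Conv1d(f1, C, k1, 1, rng)
        self.history: dict = {}

    # -- graph forward (Tensor in / Tensor out) ---------------------------

    def encode_t(self, x: Tensor) -> Tensor:
        a = self.config.leaky_slope
        h = self.enc1(x).leaky_relu(a)
        h = self.enc2(h).leaky_relu(a)
        return self.bottleneck(h).leaky_relu(a)

    def decode_t(self, z: Tensor) -> Tensor:
        a = self.config.leaky_slope
        h = self.dec1(z).leaky_relu(a)
        h = self.dec2(h).leaky_relu(a)
        return self.out(h)

    def forward_t(self, x: Tensor) -> tuple[Tensor, Tensor]:
        z = self.encode_t(x)
        return z, self.decode_t(z)

    # -- inference (numpy in / numpy out) ---------------------------------

    def _segments_of(self, batch) -> np.ndarray:
        x = batch.segments if isinstance(batch, SegmentBatch) else np.asarray(batch)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected segments of shape (N, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {x.shape}")
        return x

    def encode(self, batch, chunk: int = 512) -> np.ndarray:
        """Deterministic encoder-only forward pass -> Z of shape (N, T', D)."""
        x = self._segments_of(batch)
        return np.concatenate([
            self.encode_t(Tensor(x[i : i + chunk])).data
            for i in range(0, len(x), chunk)]) if len(x) else np.empty(
                (0, self.latent_length, self.config.latent_filters))

    def reconstruct(self, batch, chunk: int = 512) -> np.ndarray:
        x = self._segments_of(batch)
        return np.concatenate([
            self.decode_t(self.encode_t(Tensor(x[i : i + chunk]))).data
            for i in range(0, len(x), chunk)])


def build_csae(config: CSAEConfig, input_shape: tuple[int, int]) -> AutoencoderModel:
    """Build a CSAE for (T, C) segments; He-Normal init under ``config.seed``."""
    return AutoencoderModel(config, input_shape)


def encode(model: AutoencoderModel, batch) -> np.ndarray:
    return model.encode(batch)


def train_csae(model: AutoencoderModel, train: SegmentBatch, val: SegmentBatch,
               tc: TrainConfig, rng: np.random.Generator | None = None
               ) -> AutoencoderModel:
    """Unsupervised training of the composite loss with early stopping and
    best-validation restore.  ``train`` and ``val`` must be standardized and
    disjoint by trial."""
    lam = model.config.l1_coeff
    x_train = model._segments_of(train)
    x_val = model._segments_of(val)
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and val batches must be non-empty")
    if rng is None:
        rng = np.random.default_rng(model.config.seed % (2**31))

    def batch_loss(idx):
        xb = Tensor(x_train[idx])
        z, xh = model.forward_t(xb)
        loss = ((xb - xh).pow(2.0)).mean()
        if lam > 0:
            loss = loss + z.abs().sum() * (lam / len(idx))
        return loss

    def val_loss():
        total, n = 0.0, 0
        for i in range(0, len(x_val), 512):
            xb = x_val[i : i + 512]
            z = model.encode(xb)
            xh = model.reconstruct(xb)
            total += csae_loss(xb, xh, z, lam) * len(xb)
            n += len(xb)
        return total / n

    model.history = fit(model, batch_loss, val_loss, len(x_train), tc, rng)
    return model


def r2_reconstruction(model: AutoencoderModel, batch) -> float:
    """Pooled coefficient of determination of the reconstruction:
    1 - SSE/SST with SST about the batch mean over all elements."""
    x = model._segments_of(batch)
    sst = float(((x - x.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("R^2 undefined for a zero-variance batch")
    xh = model.reconstruct(batch)
    sse = float(((x - xh) ** 2).sum())
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_csae(path, model: AutoencoderModel, scaler: ScalerStats | None = None
              ) -> None:
    """Self-describing HDF5 checkpoint: schema, config, parameters, scaler."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CHECKPOINT_SCHEMA
        f.attrs["kind"] = "csae"
        f.attrs["config"] = json.dumps(asdict(model.config))
        f.attrs["input_shape"] = model.input_shape
        g = f.create_group("params")
        for name, arr in model.state_dict().items():
            g.create_dataset(name, data=arr)
        if scaler is not None:
            s = f.create_group("scaler")
            s.create_dataset("mean", data=scaler.mean)
            s.create_dataset("std", data=scaler.std)
            s.attrs["fitted_on"] = scaler.fitted_on


def load_csae(path) -> tuple[AutoencoderModel, ScalerStats | None]:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "csae":
            raise ValueError("not a CSAE checkpoint")
        config = CSAEConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in json.loads(f.attrs["config"]).items()})
        model = AutoencoderModel(config, tuple(int(v) for v in f.attrs["input_shape"]))
        model.load_state_dict({n: d[:] for n, d in f["params"].items()})
        scaler = None
        if "scaler" in f:
            scaler = ScalerStats(f["scaler"]["mean"][:], f["scaler"]["std"][:],
                                 str(f["scaler"].attrs["fitted_on"]))
    return model, scaler
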