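"""Movement classifier on frozen-encoder latent features.

The trained CSAE encoder is extracted, its weights frozen, and a light head
is trained on top: layer normalization over the feature axis (mitigating
inter-trial and inter-subject variance), one temporal 1-D convolution,
additive self-attention pooling into a context vector, a two-stage MLP and
a softmax output over the ordered class list.  Training minimizes the
categorical cross-entropy with the same AdamW / early-stopping / plateau
machinery as the autoencoder; only head parameters ever move.

Because the encoder is frozen, latent features are precomputed once per
training set, which makes head training cheap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .csae import AutoencoderModel, CSAEConfig, CHECKPOINT_SCHEMA
from .data import ScalerStats, SegmentBatch, one_hot
from .nn import (
    AttentionPool,
    Conv1d,
    Dense,
    LayerNorm,
    Module,
    Tensor,
    TrainConfig,
    fit,
)

CE_EPS = 1e-12

#: Parameter groups of a ClassifierModel, in forward order.
PARAM_GROUPS = ("encoder", "layer_norm", "conv", "attention", "mlp_fc",
                "output_softmax")


@dataclass
class ClassifierConfig:
    """Head hyperparameters; defaults: conv 64 filters kernel 3, attention
    dim 32, MLP 128 -> 64, no dropout."""

    n_classes: int
    head_conv_filters: int = 64
    head_conv_kernel: int = 3
    attention_dim: int = 32
    mlp_dims: tuple[int, int] = (128, 64)
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.mlp_dims) != 2:
            raise ValueError("the MLP head has exactly two stages")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def small_classifier_config(n_classes: int, **overrides) -> ClassifierConfig:
    """Compact head for desk-scale experiments; dropout on the MLP stages
    counteracts trial-level overfitting in small cohorts."""
    defaults = dict(head_conv_filters=24, head_conv_kernel=3,
                    attention_dim=12, mlp_dims=(48, 24), dropout=0.4)
    defaults.update(overrides)
    return ClassifierConfig(n_classes=n_classes, **defaults)


def cross_entropy(p_hat: np.ndarray, y_onehot: np.ndarray,
                  eps: float = CE_EPS) -> float:
    """Mean categorical cross-entropy: -(1/N) sum_n sum_i y'_ni log p_ni.

    Probabilities are clamped at ``eps`` before the log.
    """
    p_hat = np.asarray(p_hat, dtype=np.float64)
    y_onehot = np.asarray(y_onehot, dtype=np.float64)
    if p_hat.shape != y_onehot.shape:
        raise ValueError("probability and one-hot label shapes differ")
    return float(-(y_onehot * np.log(np.maximum(p_hat, eps))).sum(axis=1).mean())


def attention_pool(H: np.ndarray, attention: AttentionPool
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pool a (T', D) or (N, T', D) feature map into context vector(s).

    Returns (context, weights); weights are the softmax of the learned
    per-timestep importance scores and sum to one over time.
    """
    H = np.asarray(H, dtype=np.float64)
    single = H.ndim == 2
    if single:
        H = H[None]
    a = attention.scores(Tensor(H)).softmax(axis=1)
    c = (a * Tensor(H)).sum(axis=1)
    ctx, wts = c.data, a.data[..., 0]
    return (ctx[0], wts[0]) if single else (ctx, wts)


class _FrozenEncoder(Module):
    """Bitwise copy of a CSAE encoder with all parameters frozen."""

    def __init__(self, ae: AutoencoderModel):
        super().__init__()
        self.config = ae.config
        self.input_shape = ae.input_shape
        self.latent_length = ae.latent_length
        import copy

        for name in ("enc1", "enc2", "bottleneck"):
            layer = getattr(ae, name)
            clone = copy.deepcopy(layer)
            for p in clone.parameters():
                p.trainable = False
            setattr(self, name, clone)

    def __call__(self, x: Tensor) -> Tensor:
        a = self.config.leaky_slope
        h = self.enc1(x).leaky_relu(a)
        h = self.enc2(h).leaky_relu(a)
        return self.bottleneck(h).leaky_relu(a)

    def encode(self, segments: np.ndarray, chunk: int = 512) -> np.ndarray:
        x = np.asarray(segments)
        return np.concatenate([self(Tensor(x[i : i + chunk])).data
                               for i in range(0, len(x), chunk)])


class ClassifierModel(Module):
    """Frozen encoder + trainable head; predictions are row-stochastic."""

    def __init__(self, encoder: AutoencoderModel | _FrozenEncoder,
                 config: ClassifierConfig, class_list: list[str]):
        super().__init__()
        if len(class_list) != config.n_classes:
            raise ValueError("class list length must equal n_classes")
        if len(set(class_list)) != len(class_list):
            raise ValueError("class list contains duplicates")
        self.config = config
        self.class_list = [str(c) for c in class_list]
        self.encoder = (encoder if isinstance(encoder, _FrozenEncoder)
                        else _FrozenEncoder(encoder))
        D = self.encoder.config.latent_filters
        rng = np.random.default_rng(config.seed % (2**31))
        self.layer_norm = LayerNorm(D)
        self.conv = Conv1d(D, config.head_conv_filters,
                           config.head_conv_kernel, 1, rng)
        self.attention = AttentionPool(config.head_conv_filters,
                                       config.attention_dim, rng)
        self.fc1 = Dense(config.head_conv_filters, config.mlp_dims[0], rng)
        self.fc2 = Dense(config.mlp_dims[0], config.mlp_dims[1], rng)
        self.out = Dense(config.mlp_dims[1], config.n_classes, rng)
        self.history: dict = {}

    # -- parameter groups --------------------------------------------------

    def param_groups(self) -> dict[str, list]:
        return {
            "encoder": self.encoder.parameters(),
            "layer_norm": self.layer_norm.parameters(),
            "conv": self.conv.parameters(),
            "attention": self.attention.parameters(),
            "mlp_fc": self.fc1.parameters() + self.fc2.parameters(),
            "output_softmax": self.out.parameters(),
        }

    def group_digests(self) -> dict[str, str]:
        import hashlib

        out = {}
        for name, params in self.param_groups().items():
            h = hashlib.sha256()
            for p in params:
                h.update(np.ascontiguousarray(p.data).tobytes())
            out[name] = h.hexdigest()
        return out

    def apply_freeze_plan(self, plan: dict[str, bool]) -> None:
        """``plan`` maps every parameter group to trainable True/False;
        the encoder may never be made trainable here."""
        if set(plan) != set(PARAM_GROUPS):
            raise ValueError(f"freeze plan must assign exactly {PARAM_GROUPS}")
        if plan["encoder"]:
            raise ValueError("the encoder stays frozen in every protocol")
        for name, params in self.param_groups().items():
            for p in params:
                p.trainable = bool(plan[name])

    # -- forward -----------------------------------------------------------

    def head_logits_t(self, z: Tensor, drop_rng: np.random.Generator | None = None
                      ) -> Tensor:
        a = self.encoder.config.leaky_slope
        h = self.layer_norm(z)
        h = self.conv(h).leaky_relu(a)
        ctx = self.attention(h)
        h = self.fc1(ctx).leaky_relu(a)
        h = self._dropout(h, drop_rng)
        h = self.fc2(h).leaky_relu(a)
        h = self._dropout(h, drop_rng)
        return self.out(h)

    def _dropout(self, h: Tensor, drop_rng) -> Tensor:
        """Inverted dropout on the MLP stages, applied only in training."""
        p = self.config.dropout
        if drop_rng is None or p <= 0:
            return h
        mask = (drop_rng.random(h.shape) >= p) / (1.0 - p)
        return h * Tensor(mask)

    def head_probs_t(self, z: Tensor) -> Tensor:
        return self.head_logits_t(z).softmax(axis=-1)

    def penultimate_features(self, z: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Forward pass from latent features to the post-MLP representation
        (the output layer's input), without gradients."""
        a = self.encoder.config.leaky_slope
        outs = []
        for i in range(0, len(z), chunk):
            h = self.layer_norm(Tensor(z[i : i + chunk]))
            h = self.conv(h).leaky_relu(a)
            ctx = self.attention(h)
            h = self.fc1(ctx).leaky_relu(a)
            outs.append(self.fc2(h).leaky_relu(a).data)
        return np.concatenate(outs)

    def logits(self, segments, chunk: int = 512) -> np.ndarray:
        x = segments.segments if isinstance(segments, SegmentBatch) else np.asarray(segments)
        z = self.encoder.encode(x, chunk=chunk)
        return np.concatenate([self.head_logits_t(Tensor(z[i : i + chunk])).data
                               for i in range(0, len(z), chunk)])


def build_classifier(encoder: AutoencoderModel, config: ClassifierConfig,
                     class_list: list[str]) -> ClassifierModel:
    """Assemble the classifier graph over a frozen copy of ``encoder``."""
    return ClassifierModel(encoder, config, class_list)


def predict(model: ClassifierModel, batch) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (N, K) and argmax labels; argmax ties break to
    the lowest class index (deterministic)."""
    logits = model.logits(batch)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    idx = probs.argmax(axis=1)
    labels = np.array([model.class_list[i] for i in idx], dtype=object)
    return probs, labels


def _check_labels(batch: SegmentBatch, class_list: list[str],
                  require_k: int = 2) -> None:
    present = set(map(str, batch.labels))
    unknown = present - set(class_list)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class list {class_list}")
    if len(present) < require_k:
        raise ValueError(
            f"training requires at least {require_k} distinct classes with "
            f"samples; got {sorted(present)}")


def _train_head(model: ClassifierModel, train: SegmentBatch, val: SegmentBatch,
                tc: TrainConfig, rng: np.random.Generator) -> dict:
    """Shared supervised loop over precomputed latent features."""
    z_train = model.encoder.encode(train.segments)
    z_val = model.encoder.encode(val.segments)
    y_train = one_hot(train.labels, model.class_list)
    y_val = one_hot(val.labels, model.class_list)

    def batch_loss(idx):
        logits = model.head_logits_t(Tensor(z_train[idx]), drop_rng=rng)
        p = logits.softmax(axis=-1)
        return -(Tensor(y_train[idx]) * p.clip_min(CE_EPS).log()).sum(axis=1).mean()

    def val_loss():
        total = 0.0
        for i in range(0, len(z_val), 1024):
            p = model.head_probs_t(Tensor(z_val[i : i + 1024])).data
            total += cross_entropy(p, y_val[i : i + 1024]) * min(1024, len(z_val) - i)
        return total / len(z_val)

    return fit(model, batch_loss, val_loss, len(z_train), tc, rng)


def train_classifier(model: ClassifierModel, train: SegmentBatch,
                     val: SegmentBatch, tc: TrainConfig,
                     rng: np.random.Generator | None = None) -> ClassifierModel:
    """Train all head groups (encoder frozen) by cross-entropy minimization."""
    _check_labels(train, model.class_list)
    _check_labels(val, model.class_list, require_k=1)
    model.apply_freeze_plan({
        "encoder": False, "layer_norm": True, "conv": True,
        "attention": True, "mlp_fc": True, "output_softmax": True})
    if rng is None:
        rng = np.random.default_rng(model.config.seed % (2**31))
    model.history = _train_head(model, train, val, tc, rng)
    return model


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_classifier(path, model: ClassifierModel,
                    scaler: ScalerStats | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = CHECKPOINT_SCHEMA
        f.attrs["kind"] = "classifier"
        f.attrs["config"] = json.dumps(asdict(model.config))
        f.attrs["encoder_config"] = json.dumps(asdict(model.encoder.config))
        f.attrs["input_shape"] = model.encoder.input_shape
        f.attrs["class_list"] = json.dumps(model.class_list)
        g = f.create_group("params")
        for name, arr in model.state_dict().items():
            g.create_dataset(name, data=arr)
        if scaler is not None:
            s = f.create_group("scaler")
            s.create_dataset("mean", data=scaler.mean)
            s.create_dataset("std", data=scaler.std)
            s.attrs["fitted_on"] = scaler.fitted_on


def load_classifier(path) -> tuple[ClassifierModel, ScalerStats | None]:
    from .csae import build_csae

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "classifier":
            raise ValueError("not a classifier checkpoint")
        cfg = ClassifierConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in json.loads(f.attrs["config"]).items()})
        enc_cfg = CSAEConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in json.loads(f.attrs["encoder_config"]).items()})
        shape = tuple(int(v) for v in f.attrs["input_shape"])
        model = ClassifierModel(build_csae(enc_cfg, shape), cfg,
                                json.loads(f.attrs["class_list"]))
        model.load_state_dict({n: d[:] for n, d in f["params"].items()})
        scaler = None
        if "scaler" in f:
            scaler = ScalerStats(f["scaler"]["mean"][:], f["scaler"]["std"][:],
                                 str(f["scaler"].attrs["fitted_on"]))
    return model, scaler
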