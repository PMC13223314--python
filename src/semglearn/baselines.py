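"""Benchmark methods and model-cost accounting.

Four reference pipelines put the CSAE classifier in context:

* classical time-domain features (the Hudgins-style set) + random forest,
* a fully-connected autoencoder (FCAE) over the flattened segment + random
  forest on its bottleneck features — the temporal-structure ablation,
* a non-sparse CAE — simply the CSAE with ``l1_coeff=0``,
* a supervised end-to-end CNN-LSTM of comparable parameter capacity.

All baselines consume the same fold splits and the same train-fitted scaler
as the main pipeline.  :func:`model_cost_report` derives parameter counts,
static/runtime memory and FLOPs analytically from layer shapes
(multiply-accumulate = 2 FLOPs; 4 bytes per parameter, the single-precision
deployment convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .classifier import ClassifierModel
from .csae import AutoencoderModel
from .data import SegmentBatch, one_hot
from .nn import (
    Conv1d,
    ConvTranspose1d,
    Dense,
    LSTM,
    Module,
    Tensor,
    TrainConfig,
    fit,
)

CLASSICAL_FEATURE_NAMES = ("mav", "var", "zc", "wl", "ssc", "rms")

#: Threshold for zero-crossing / slope-sign-change counting on standardized
#: signals (amplitude is already normalized, so no dead-band is applied).
ZC_THRESHOLD = 0.0


def classical_features(segment: np.ndarray) -> np.ndarray:
    """Hudgins-style time-domain features per channel, concatenated.

    For a (T, C) segment returns length 6*C: mean absolute value, variance,
    zero crossings, waveform length, slope-sign changes, root mean square
    (channel-major order).
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("segment must be (T, C) with T >= 2")
    mav = np.abs(x).mean(axis=0)
    var = x.var(axis=0, ddof=0)
    signs = np.sign(x)
    signs[signs == 0] = 1.0  # exact zeros count with the positive side
    zc = (np.diff(signs, axis=0) != 0).sum(axis=0).astype(float)
    wl = np.abs(np.diff(x, axis=0)).sum(axis=0)
    dx = np.diff(x, axis=0)
    ssc = (dx[:-1] * dx[1:] < -ZC_THRESHOLD).sum(axis=0).astype(float)
    rms = np.sqrt((x**2).mean(axis=0))
    return np.concatenate([np.stack([mav, var, zc, wl, ssc, rms], axis=0)[:, c]
                           for c in range(x.shape[1])])


def batch_classical_features(batch: SegmentBatch) -> np.ndarray:
    return np.stack([classical_features(s) for s in batch.segments])


def train_rf_baseline(features: np.ndarray, labels, seed: int = 0,
                      n_estimators: int = 200) -> RandomForestClassifier:
    """Random forest on a flat feature matrix, fixed seed for reproducibility."""
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(np.asarray(features), np.asarray(labels).astype(str))
    return rf


# ---------------------------------------------------------------------------
# Fully-connected autoencoder (flattened input)
# ---------------------------------------------------------------------------


class FCAEModel(Module):
    """Dense autoencoder over the flattened (T*C,) segment.

    Flattening discards the signal's temporal locality: the dense layers see
    an arbitrary fixed permutation of samples, which is the architectural
    contrast the temporal presets expose.
    """

    def __init__(self, input_dim: int, hidden: tuple[int, ...],
                 bottleneck: int, seed: int = 0, leaky_slope: float = 0.01):
        super().__init__()
        self.input_dim = input_dim
        self.bottleneck_dim = bottleneck
        self.leaky_slope = leaky_slope
        rng = np.random.default_rng(seed % (2**31))
        dims = [input_dim, *hidden, bottleneck]
        self.enc_layers = [Dense(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dec_layers = [Dense(a, b, rng)
                           for a, b in zip(dims[::-1][:-1], dims[::-1][1:])]
        for i, lyr in enumerate(self.enc_layers):
            setattr(self, f"enc{i}", lyr)
        for i, lyr in enumerate(self.dec_layers):
            setattr(self, f"dec{i}", lyr)
        self.history: dict = {}

    def encode_t(self, x: Tensor) -> Tensor:
        h = x
        for lyr in self.enc_layers:
            h = lyr(h).leaky_relu(self.leaky_slope)
        return h

    def decode_t(self, z: Tensor) -> Tensor:
        h = z
        for lyr in self.dec_layers[:-1]:
            h = lyr(h).leaky_relu(self.leaky_slope)
        return self.dec_layers[-1](h)

    def encode(self, batch, chunk: int = 1024) -> np.ndarray:
        x = self._flatten(batch)
        return np.concatenate([self.encode_t(Tensor(x[i : i + chunk])).data
                               for i in range(0, len(x), chunk)])

    def reconstruct_segments(self, batch, shape: tuple[int, int]) -> np.ndarray:
        x = self._flatten(batch)
        out = np.concatenate([
            self.decode_t(self.encode_t(Tensor(x[i : i + 1024]))).data
            for i in range(0, len(x), 1024)])
        return out.reshape(-1, *shape)

    def _flatten(self, batch) -> np.ndarray:
        x = batch.segments if isinstance(batch, SegmentBatch) else np.asarray(batch)
        if x.ndim == 3:
            x = x.reshape(len(x), -1)
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected flattened dim {self.input_dim}, got {x.shape[1]}")
        return x


def build_fcae(input_dim: int, hidden: tuple[int, ...] = (512, 128),
               bottleneck: int = 32, seed: int = 0) -> FCAEModel:
    """FCAE with the default 2000 -> 512 -> 128 -> bottleneck mirror."""
    return FCAEModel(input_dim, hidden, bottleneck, seed=seed)


def train_fcae(model: FCAEModel, train: SegmentBatch, val: SegmentBatch,
               tc: TrainConfig, rng: np.random.Generator | None = None
               ) -> FCAEModel:
    """Reconstruction-only training (no sparsity penalty)."""
    x_train = model._flatten(train)
    x_val = model._flatten(val)
    if rng is None:
        rng = np.random.default_rng(0)

    def batch_loss(idx):
        xb = Tensor(x_train[idx])
        return ((xb - model.decode_t(model.encode_t(xb))).pow(2.0)).mean()

    def val_loss():
        total = 0.0
        for i in range(0, len(x_val), 1024):
            xb = x_val[i : i + 1024]
            xh = model.decode_t(model.encode_t(Tensor(xb))).data
            total += float(((xb - xh) ** 2).mean()) * len(xb)
        return total / len(x_val)

    model.history = fit(model, batch_loss, val_loss, len(x_train), tc, rng)
    return model


# ---------------------------------------------------------------------------
# Supervised CNN-LSTM
# ---------------------------------------------------------------------------


class CNNLSTMModel(Module):
    """Conv front-end + LSTM + dense softmax, trained end-to-end."""

    def __init__(self, input_shape: tuple[int, int], n_classes: int,
                 conv_filters: tuple[int, int] = (16, 32),
                 conv_kernels: tuple[int, int] = (7, 5),
                 conv_strides: tuple[int, int] = (5, 2),
                 lstm_hidden: int = 24, seed: int = 0,
                 leaky_slope: float = 0.01):
        super().__init__()
        T, C = input_shape
        self.input_shape = input_shape
        self.leaky_slope = leaky_slope
        self.class_list: list[str] = []
        rng = np.random.default_rng(seed % (2**31))
        self.conv1 = Conv1d(C, conv_filters[0], conv_kernels[0], conv_strides[0], rng)
        self.conv2 = Conv1d(conv_filters[0], conv_filters[1], conv_kernels[1],
                            conv_strides[1], rng)
        self.lstm = LSTM(conv_filters[1], lstm_hidden, rng)
        self.out = Dense(lstm_hidden, n_classes, rng)
        self.history: dict = {}

    def logits_t(self, x: Tensor) -> Tensor:
        h = self.conv1(x).leaky_relu(self.leaky_slope)
        h = self.conv2(h).leaky_relu(self.leaky_slope)
        return self.out(self.lstm(h))

    def predict(self, batch, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
        x = batch.segments if isinstance(batch, SegmentBatch) else np.asarray(batch)
        logits = np.concatenate([self.logits_t(Tensor(x[i : i + chunk])).data
                                 for i in range(0, len(x), chunk)])
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        labels = np.array([self.class_list[i] for i in probs.argmax(axis=1)],
                          dtype=object)
        return probs, labels


def parameter_count(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def build_cnn_lstm(input_shape: tuple[int, int], n_classes: int,
                   reference: Module | None = None,
                   capacity_tolerance: float = 0.2, seed: int = 0,
                   **kwargs) -> CNNLSTMModel:
    """Build the CNN-LSTM; if a reference model is given, warn when the
    trainable-parameter counts differ by more than the tolerance."""
    model = CNNLSTMModel(input_shape, n_classes, seed=seed, **kwargs)
    if reference is not None:
        n_ref = parameter_count(reference)
        n_new = parameter_count(model)
        if abs(n_new - n_ref) > capacity_tolerance * n_ref:
            warnings.warn(
                f"capacity mismatch: CNN-LSTM has {n_new} parameters vs "
                f"reference {n_ref} (tolerance {capacity_tolerance:.0%})",
                RuntimeWarning, stacklevel=2)
    return model


def train_cnn_lstm(model: CNNLSTMModel, train: SegmentBatch, val: SegmentBatch,
                   class_list: list[str], tc: TrainConfig,
                   rng: np.random.Generator | None = None) -> CNNLSTMModel:
    """End-to-end supervised training with the shared loop."""
    from .classifier import CE_EPS, cross_entropy

    model.class_list = [str(c) for c in class_list]
    x_train, x_val = train.segments, val.segments
    y_train = one_hot(train.labels, model.class_list)
    y_val = one_hot(val.labels, model.class_list)
    if rng is None:
        rng = np.random.default_rng(0)

    def batch_loss(idx):
        p = model.logits_t(Tensor(x_train[idx])).softmax(axis=-1)
        return -(Tensor(y_train[idx]) * p.clip_min(CE_EPS).log()).sum(axis=1).mean()

    def val_loss():
        total = 0.0
        for i in range(0, len(x_val), 256):
            p, _ = model.predict(x_val[i : i + 256])
            total += cross_entropy(p, y_val[i : i + 256]) * len(p)
        return total / len(x_val)

    model.history = fit(model, batch_loss, val_loss, len(x_train), tc, rng)
    return model


# ---------------------------------------------------------------------------
# Model-cost accounting
# ---------------------------------------------------------------------------


@dataclass
class CostReport:
    parameter_count: int
    static_bytes: int
    runtime_bytes_estimate: int
    flops_per_inference: float

    @property
    def static_mb(self) -> float:
        return self.static_bytes / 2**20

    @property
    def runtime_mb(self) -> float:
        return self.runtime_bytes_estimate / 2**20

    @property
    def gflops(self) -> float:
        return self.flops_per_inference / 1e9


BENCHMARK_METHODS = ("csae", "cae0", "fcae", "classical_rf", "cnn_lstm")


def benchmark_table(cohort, methods=BENCHMARK_METHODS, *, csae_config=None,
                    clf_config=None, tc_csae=None, tc_clf=None,
                    window_ms: float = 250.0, stride_ms: float = 125.0,
                    seed: int = 0, folds=None, fcae_hidden=(512, 128),
                    fcae_bottleneck: int = 32):
    """Cross-validated comparison of the benchmark methods.

    Every method consumes the identical LOSO fold splits and the identical
    train-fitted scaler (shared-harness contract).  Returns a DataFrame with
    one row per method: mean/SE micro-F1 across the selected folds plus the
    analytic cost columns (parameters, static MB, runtime MB, GFLOPs; the
    classical pipeline has no stored network, so its memory columns are 0).
    """
    import pandas as pd

    from .classifier import ClassifierConfig, build_classifier, predict, train_classifier
    from .csae import CSAEConfig, build_csae, train_csae
    from .data import apply_scaler, fit_scaler, make_loso_folds, segment_cohort
    from .evaluation import _fold_seed, class_order, prf1

    csae_config = csae_config or CSAEConfig()
    clf_config = clf_config or ClassifierConfig(n_classes=2)
    tc_csae = tc_csae or TrainConfig()
    tc_clf = tc_clf or TrainConfig()
    classes = class_order(cohort)
    batch = segment_cohort(cohort, window_ms, stride_ms)
    plans = make_loso_folds(cohort)
    indices = list(range(len(plans))) if folds is None else list(folds)
    T, C = batch.segments.shape[1:]

    from dataclasses import replace as _replace

    scores: dict[str, list[float]] = {m: [] for m in methods}
    costs: dict[str, CostReport | None] = {}
    for fi in indices:
        plan = plans[fi]
        fseed = _fold_seed(seed, fi, salt=13)
        src = batch.select(subjects=plan.source_subjects)
        train = src.select(trials=plan.source_train_trials)
        scaler = fit_scaler(train)
        train_s = apply_scaler(train, scaler)
        val_s = apply_scaler(src.select(trials=plan.source_val_trials), scaler)
        test_s = apply_scaler(src.select(trials=plan.source_test_trials), scaler)
        y_test = test_s.labels.astype(str)

        ref_clf = None
        for method in methods:
            if method in ("csae", "cae0"):
                cfg = _replace(csae_config, seed=fseed,
                               l1_coeff=0.0 if method == "cae0"
                               else csae_config.l1_coeff)
                ae = build_csae(cfg, (T, C))
                train_csae(ae, train_s, val_s, tc_csae)
                ccfg = _replace(clf_config, n_classes=len(classes), seed=fseed + 1)
                clf = build_classifier(ae, ccfg, classes)
                train_classifier(clf, train_s, val_s, tc_clf)
                _, labels = predict(clf, test_s)
                if method == "csae":
                    ref_clf = clf
                costs.setdefault(method, model_cost_report(clf))
            elif method == "fcae":
                fc = build_fcae(T * C, fcae_hidden, fcae_bottleneck, seed=fseed)
                train_fcae(fc, train_s, val_s, tc_csae,
                           rng=np.random.default_rng(fseed + 5))
                rf = train_rf_baseline(fc.encode(train_s), train_s.labels,
                                       seed=fseed + 6)
                labels = rf.predict(fc.encode(test_s))
                costs.setdefault(method, model_cost_report(fc))
            elif method == "classical_rf":
                rf = train_rf_baseline(batch_classical_features(train_s),
                                       train_s.labels, seed=fseed + 7)
                labels = rf.predict(batch_classical_features(test_s))
                costs.setdefault(method, CostReport(0, 0, 0,
                                                    2.0 * 10 * T * C))
            elif method == "cnn_lstm":
                net = build_cnn_lstm((T, C), len(classes), reference=ref_clf,
                                     seed=fseed + 8)
                train_cnn_lstm(net, train_s, val_s, classes, tc_clf,
                               rng=np.random.default_rng(fseed + 9))
                _, labels = net.predict(test_s)
                costs.setdefault(method, model_cost_report(net))
            else:
                raise ValueError(f"unknown method {method!r}")
            scores[method].append(prf1(y_test, labels, classes).micro_f1)

    rows = []
    for method in methods:
        x = np.array(scores[method])
        cost = costs[method]
        rows.append({
            "method": method,
            "f1_mean": float(x.mean()),
            "f1_se": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
            "parameters": cost.parameter_count,
            "static_mb": cost.static_mb,
            "runtime_mb": cost.runtime_mb,
            "gflops": cost.gflops,
        })
    return pd.DataFrame(rows)


_BYTES_PER_PARAM = 4    # single-precision deployment
_BYTES_PER_ACT = 4


def _layer_costs(layer, t_in: int, c_in: int):
    """(t_out, c_out, macs) for one layer processing a (t_in, c_in) map."""
    if isinstance(layer, Conv1d):
        t_out = -(-t_in // layer.stride)
        k, c, f = layer.w.data.shape
        return t_out, f, t_out * k * c * f
    if isinstance(layer, ConvTranspose1d):
        k, c, f = layer.w.data.shape
        return t_in * layer.stride, f, t_in * k * c * f
    if isinstance(layer, Dense):
        d_in, d_out = layer.w.data.shape
        return 1, d_out, d_in * d_out
    if isinstance(layer, LSTM):
        h = layer.d_hidden
        d_in = layer.wx.data.shape[0]
        return 1, h, t_in * 4 * h * (d_in + h)
    raise TypeError(f"no cost model for {type(layer).__name__}")


def _inference_path(model) -> tuple[list, tuple[int, int]]:
    """Ordered layer list and input (T, C) for one inference pass."""
    if isinstance(model, ClassifierModel):
        enc = model.encoder
        layers = [enc.enc1, enc.enc2, enc.bottleneck, model.conv,
                  model.attention, model.fc1, model.fc2, model.out]
        return layers, enc.input_shape
    if isinstance(model, AutoencoderModel):
        return ([model.enc1, model.enc2, model.bottleneck, model.dec1,
                 model.dec2, model.out], model.input_shape)
    if isinstance(model, CNNLSTMModel):
        return [model.conv1, model.conv2, model.lstm, model.out], model.input_shape
    if isinstance(model, FCAEModel):
        return model.enc_layers + model.dec_layers, (1, model.input_dim)
    raise TypeError(f"no inference path for {type(model).__name__}")


def model_cost_report(model: Module) -> CostReport:
    """Analytic cost of one forward pass, derived from layer shapes only.

    Conventions: one multiply-accumulate = 2 FLOPs; parameters stored at 4
    bytes; runtime memory approximated as the two largest consecutive
    activation buffers plus the parameters (all at 4 bytes/value).  The
    report depends on the architecture alone, never on parameter values.
    """
    layers, (t, c) = _inference_path(model)
    total_macs = 0
    act_sizes = [t * c]
    for layer in layers:
        if hasattr(layer, "scores"):  # attention pooling
            d_in, d_attn = layer.w.data.shape
            total_macs += t * (d_in * d_attn + d_attn) + t * d_in
            act_sizes.append(d_in)
            t, c = 1, d_in
            continue
        t, c, macs = _layer_costs(layer, t, c)
        total_macs += macs
        act_sizes.append(t * c)
    n_params = parameter_count(model)
    peak_pair = max(a + b for a, b in zip(act_sizes[:-1], act_sizes[1:]))
    return CostReport(
        parameter_count=n_params,
        static_bytes=n_params * _BYTES_PER_PARAM,
        runtime_bytes_estimate=(peak_pair * _BYTES_PER_ACT
                                + n_params * _BYTES_PER_PARAM),
        flops_per_inference=2.0 * total_macs)
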