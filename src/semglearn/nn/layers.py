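"""Neural-network layers built on the :mod:`semglearn.nn.tensor` autograd.

All temporal layers use the (N, T, C) layout: batch, time, channels.
1-D convolutions use "same"-style padding so that a strided convolution maps
a length-T sequence to ceil(T/S), and the mirrored transposed convolution
maps T' back to T'*S — the shape symmetry the autoencoder relies on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Parameter, Tensor


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-Normal initialization: N(0, sqrt(2/fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _same_pad(T: int, K: int, S: int) -> tuple[int, int, int]:
    """Return (T_out, pad_left, pad_right) for same-padded stride-S conv."""
    T_out = -(-T // S)  # ceil
    pad_total = max((T_out - 1) * S + K - T, 0)
    pad_left = pad_total // 2
    return T_out, pad_left, pad_total - pad_left


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Strided 1-D convolution.

    x: (N, T, Cin); w: (K, Cin, F); b: (F,) -> (N, ceil(T/S), F).
    """
    N, T, Cin = x.data.shape
    K, Cin_w, F = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
    T_out, pl, pr = _same_pad(T, K, stride)
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    # windows: (N, n_positions, Cin, K) -> strided subset (N, T_out, Cin, K)
    xw = sliding_window_view(xp, K, axis=1)[:, :: stride][:, :T_out]
    y = np.tensordot(xw, w.data, axes=((3, 2), (0, 1))) + b.data
    out = Tensor(y, _prev=(x, w, b))

    def bwd(g):
        # g: (N, T_out, F)
        gw = np.tensordot(xw, g, axes=((0, 1), (0, 1)))  # (Cin, K, F)
        w._accumulate(np.transpose(gw, (1, 0, 2)))
        b._accumulate(g.sum(axis=(0, 1)))
        gxp = np.zeros_like(xp)
        for k in range(K):
            # positions t*S + k for t in [0, T_out)
            gxp[:, k : k + stride * T_out : stride, :] += g @ w.data[k].T
        x._accumulate(gxp[:, pl : pl + T, :])

    out._backward = bwd
    return out


def conv_transpose1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Transposed 1-D convolution mirroring a same-padded stride-S conv.

    x: (N, T', Cin); w: (K, Cin, F); b: (F,) -> (N, T'*S, F).
    """
    N, Tp, Cin = x.data.shape
    K, Cin_w, F = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input has {Cin}, weight expects {Cin_w}")
    T_out = Tp * stride
    # padding of the conv this op mirrors (length T_out -> Tp)
    _, pl, _ = _same_pad(T_out, K, stride)
    full_len = max((Tp - 1) * stride + K, pl + T_out)
    full = np.zeros((N, full_len, F))
    for k in range(K):
        full[:, k : k + stride * Tp : stride, :] += x.data @ w.data[k]
    y = full[:, pl : pl + T_out, :] + b.data
    out = Tensor(y, _prev=(x, w, b))

    def bwd(g):
        gfull = np.zeros((N, full_len, F))
        gfull[:, pl : pl + T_out, :] = g
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for k in range(K):
            sl = gfull[:, k : k + stride * Tp : stride, :]
            gx += sl @ w.data[k].T
            gw[k] = np.tensordot(x.data, sl, axes=((0, 1), (0, 1)))
        x._accumulate(gx)
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 1)))

    out._backward = bwd
    return out


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for n, p in self._params.items():
            out[f"{prefix}{n}"] = p
        for n, m in self._modules.items():
            out.update(m.named_parameters(prefix=f"{prefix}{n}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(state) != set(params):
            raise ValueError("state dict keys do not match module parameters")
        for n, p in params.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}")
            p.data = state[n].copy()

    def digest(self) -> str:
        """SHA-256 over all parameter bytes, for freeze-contract checks."""
        import hashlib

        h = hashlib.sha256()
        for n in sorted(self.named_parameters()):
            h.update(n.encode())
            h.update(np.ascontiguousarray(self.named_parameters()[n].data).tobytes())
        return h.hexdigest()


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.w = Parameter(he_normal(rng, (kernel, in_ch, out_ch), kernel * in_ch))
        self.b = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.stride)


class ConvTranspose1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.w = Parameter(he_normal(rng, (kernel, in_ch, out_ch), kernel * in_ch))
        self.b = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.w, self.b, self.stride)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(he_normal(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Normalization over the trailing (feature) axis, per timestep."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return xc * inv * self.gamma + self.beta


class AttentionPool(Module):
    """Additive self-attention over time: e_t = v . tanh(W h_t + b)."""

    def __init__(self, d_in: int, d_attn: int, rng: np.random.Generator):
        super().__init__()
        self.w = Parameter(he_normal(rng, (d_in, d_attn), d_in))
        self.b = Parameter(np.zeros(d_attn))
        self.v = Parameter(he_normal(rng, (d_attn, 1), d_attn))

    def scores(self, h: Tensor) -> Tensor:
        """Unnormalized importance scores, shape (N, T, 1)."""
        return (h @ self.w + self.b).tanh() @ self.v

    def __call__(self, h: Tensor) -> Tensor:
        a = self.scores(h).softmax(axis=1)  # (N, T, 1)
        return (a * h).sum(axis=1)  # (N, D)

    def weights(self, h: np.ndarray) -> np.ndarray:
        """Attention weights for introspection (numpy in / numpy out)."""
        a = self.scores(Tensor(h)).softmax(axis=1)
        return a.data[..., 0]


class LSTM(Module):
    """Single-layer LSTM; returns the final hidden state (N, H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.d_hidden = d_hidden
        self.wx = Parameter(he_normal(rng, (d_in, 4 * d_hidden), d_in))
        self.wh = Parameter(he_normal(rng, (d_hidden, 4 * d_hidden), d_hidden))
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)

    def __call__(self, x: Tensor) -> Tensor:
        N, T, _ = x.data.shape
        H = self.d_hidden
        h = Tensor(np.zeros((N, H)))
        c = Tensor(np.zeros((N, H)))
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.wx + h @ self.wh + self.b
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h
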