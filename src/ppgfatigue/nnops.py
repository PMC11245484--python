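"""Neural-network primitives in plain numpy, with exact manual backprop.

Everything runs in float64 on CPU, which keeps the arithmetic transparent
and lets the backward passes be verified against finite differences to
tight tolerances.  Shapes follow the 1-D convention (batch, channels, time)
for convolutional layers and (batch, time, features) for recurrent ones.

The update rule implemented by :func:`sgd_step` is SGD with momentum and
decoupled weight decay,

    dW(t+1) = -(lr * wd / r) * W - (lr / batch) * dC/dW + momentum * dW(t),

where ``r`` is the training-set size and ``dC/dW`` the gradient of the
batch-summed cross-entropy; bias updates carry no decay term.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# parameters and module plumbing


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("name", "value", "grad", "is_bias")

    def __init__(self, name: str, value: np.ndarray, is_bias: bool = False):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.is_bias = is_bias


class Module:
    """Minimal layer base: forward caches what backward needs."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
    # caches are per-call; zeroing grads is the trainer's job
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# convolution


def _pad_amounts(t: int, k: int, stride: int, padding: str) -> tuple[int, int, int]:
    """(pad_left, pad_right, t_out) for 'valid' or 'same' padding."""
    if padding == "valid":
        if k > t:
            raise ValueError(f"kernel length {k} exceeds input length {t}")
        return 0, 0, (t - k) // stride + 1
    if padding == "same":
        t_out = -(-t // stride)  # ceil
        total = max((t_out - 1) * stride + k - t, 0)
        return total // 2, total - total // 2, t_out
    raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")


def _conv_windows(x: np.ndarray, k: int, stride: int, padding: str):
    b, c, t = x.shape
    pl, pr, t_out = _pad_amounts(t, k, stride, padding)
    xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
    win = sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]
    return xp, win[:, :, :t_out], pl, t_out


def _scatter_windows(gwin: np.ndarray, xp_shape, k: int, stride: int, pl: int, t: int):
    """Adjoint of window extraction: scatter-add window grads back to the input."""
    dxp = np.zeros(xp_shape)
    t_out = gwin.shape[2]
    for kk in range(k):
        dxp[:, :, kk : kk + stride * (t_out - 1) + 1 : stride] += gwin[:, :, :, kk]
    return dxp[:, :, pl : pl + t]


_ACTIVATIONS = {
    "identity": (lambda z: z, lambda z, a: np.ones_like(a)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda z, a: a * (1.0 - a)),
}


def conv1d_forward(
    inputs: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str = "identity",
    stride: int = 1,
    padding: str = "valid",
) -> np.ndarray:
    """Multi-channel 1-D convolution (cross-correlation, CNN convention).

    ``inputs`` is (C_in, T) or (B, C_in, T); ``kernels`` is (C_out, C_in, K);
    output map j is activation(sum_i inputs_i * k_ij + b_j).
    """
    x = np.asarray(inputs, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    W = np.asarray(kernels, dtype=float)
    b = np.asarray(biases, dtype=float)
    if x.ndim != 3 or W.ndim != 3:
        raise ValueError(
            f"expected inputs (B, C_in, T) and kernels (C_out, C_in, K), got "
            f"{x.shape} and {W.shape}"
        )
    if x.shape[1] != W.shape[1]:
        raise ValueError(
            f"input channels {x.shape[1]} do not match kernel channels {W.shape[1]}"
        )
    if b.shape != (W.shape[0],):
        raise ValueError(f"biases must have shape ({W.shape[0]},), got {b.shape}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    _, win, _, _ = _conv_windows(x, W.shape[2], stride, padding)
    z = np.einsum("bctk,ock->bot", win, W, optimize=True) + b[:, None]
    act, _ = _ACTIVATIONS[activation]
    y = act(z)
    return y[0] if squeeze else y


class Conv1d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: str = "same",
        activation: str = "identity",
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        self.W = Param(f"{name}.W", _uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.b = Param(f"{name}.b", np.zeros(out_channels), is_bias=True)
        self.stride = stride
        self.padding = padding
        self.activation = activation

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.W.value.shape[2]
        xp, win, pl, _ = _conv_windows(x, k, self.stride, self.padding)
        z = np.einsum("bctk,ock->bot", win, self.W.value, optimize=True) + self.b.value[:, None]
        act, _ = _ACTIVATIONS[self.activation]
        y = act(z)
        self._cache = (x.shape, xp.shape, win, pl, z, y)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, win, pl, z, y = self._cache
        _, dact = _ACTIVATIONS[self.activation]
        gz = gy * dact(z, y)
        self.W.grad += np.einsum("bot,bctk->ock", gz, win, optimize=True)
        self.b.grad += gz.sum(axis=(0, 2))
        gwin = np.einsum("bot,ock->bctk", gz, self.W.value, optimize=True)
        return _scatter_windows(gwin, xp_shape, self.W.value.shape[2], self.stride, pl, x_shape[2])


class DepthwiseConv1d(Module):
    """Per-channel convolution, the first half of a depthwise-separable conv."""

    def __init__(
        self,
        channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
        name: str = "dwconv",
    ):
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", _uniform_init(rng, (channels, kernel_size), kernel_size))
        self.b = Param(f"{name}.b", np.zeros(channels), is_bias=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.W.value.shape[1]
        xp, win, pl, _ = _conv_windows(x, k, self.stride, self.padding)
        y = np.einsum("bctk,ck->bct", win, self.W.value, optimize=True) + self.b.value[:, None]
        self._cache = (x.shape, xp.shape, win, pl)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, win, pl = self._cache
        self.W.grad += np.einsum("bct,bctk->ck", gy, win, optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        gwin = np.einsum("bct,ck->bctk", gy, self.W.value, optimize=True)
        return _scatter_windows(gwin, xp_shape, self.W.value.shape[1], self.stride, pl, x_shape[2])


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class AvgPoolTime(Module):
    """Non-overlapping temporal average pooling by an integer factor on (B, C, T)."""

    def __init__(self, factor: int):
        if factor < 1:
            raise ValueError("pooling factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, t = x.shape
        t_out = t // self.factor
        self._t = t
        return x[:, :, : t_out * self.factor].reshape(b, c, t_out, self.factor).mean(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, t_out = gy.shape
        gx = np.zeros((b, c, self._t))
        spread = np.repeat(gy / self.factor, self.factor, axis=2)
        gx[:, :, : t_out * self.factor] = spread
        return gx


class Transpose(Module):
    """(B, C, T) <-> (B, T, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.swapaxes(x, 1, 2))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(np.swapaxes(gy, 1, 2))


class MeanOverTime(Module):
    """(B, T, F) -> (B, F) by averaging over time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, None, :], self._t, axis=1) / self._t


class LayerNorm(Module):
    """Feature-axis normalisation with learnable gain and shift, on (..., F).

    Keeps the scale of extractor outputs bounded so downstream recurrent
    gates do not saturate; without it, deep unnormalised conv stacks train
    erratically across seeds.
    """

    def __init__(self, dim: int, name: str = "ln", eps: float = 1e-6):
        self.gain = Param(f"{name}.gain", np.ones(dim))
        self.shift = Param(f"{name}.shift", np.zeros(dim), is_bias=True)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gain.value * xhat + self.shift.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(gy.ndim - 1))
        self.gain.grad += (gy * xhat).sum(axis=axes)
        self.shift.grad += gy.sum(axis=axes)
        gxhat = gy * self.gain.value
        m1 = gxhat.mean(axis=-1, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (gxhat - m1 - xhat * m2)


class ChannelNorm(Module):
    """Per-sample, per-channel normalisation over time on (B, C, T).

    The batch-independent stand-in for the batch normalisation a standard
    residual / separable stack would carry: it re-centres every channel's
    pre-activations, so ReLUs cannot die collectively and training is stable
    across seeds.  Learnable per-channel gain and shift.
    """

    def __init__(self, channels: int, name: str = "cn", eps: float = 1e-6):
        self.gain = Param(f"{name}.gain", np.ones((channels, 1)))
        self.shift = Param(f"{name}.shift", np.zeros((channels, 1)), is_bias=True)
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gain.value * xhat + self.shift.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gain.grad += (gy * xhat).sum(axis=(0, 2))[:, None]
        self.shift.grad += gy.sum(axis=(0, 2))[:, None]
        gxhat = gy * self.gain.value
        m1 = gxhat.mean(axis=2, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=2, keepdims=True)
        return inv * (gxhat - m1 - xhat * m2)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.W = Param(f"{name}.W", _uniform_init(rng, (out_dim, in_dim), in_dim))
        self.b = Param(f"{name}.b", np.zeros(out_dim), is_bias=True)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += gy.T @ self._x
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value


class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class ResidualBlock(Module):
    """Two same-padded convolutions with an identity (or projected) shortcut."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "res",
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, stride, "same", "identity", rng, f"{name}.conv1")
        self.norm1 = ChannelNorm(out_channels, f"{name}.norm1")
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, 1, "same", "identity", rng, f"{name}.conv2")
        self.norm2 = ChannelNorm(out_channels, f"{name}.norm2")
        self.project = None
        if stride != 1 or in_channels != out_channels:
            self.project = Conv1d(in_channels, out_channels, 1, stride, "same", "identity", rng, f"{name}.proj")
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.norm2.forward(
            self.conv2.forward(self.relu1.forward(self.norm1.forward(self.conv1.forward(x))))
        )
        short = self.project.forward(x) if self.project is not None else x
        return self.relu_out.forward(main + short)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(gy)
        gx_main = self.conv1.backward(
            self.norm1.backward(self.relu1.backward(self.conv2.backward(self.norm2.backward(g))))
        )
        gx_short = self.project.backward(g) if self.project is not None else g
        return gx_main + gx_short

    @property
    def n_weighted_layers(self) -> int:
        # main-path convolutions only; the shortcut projection is not counted
        return 2


class SeparableConv(Module):
    """Depthwise convolution followed by a pointwise (1x1) mix, then ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "sep",
    ):
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv1d(in_channels, kernel_size, stride, "same", rng, f"{name}.dw")
        self.pointwise = Conv1d(in_channels, out_channels, 1, 1, "same", "identity", rng, f"{name}.pw")
        self.norm = ChannelNorm(out_channels, f"{name}.norm")
        self.relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(
            self.norm.forward(self.pointwise.forward(self.depthwise.forward(x)))
        )

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(
            self.pointwise.backward(self.norm.backward(self.relu.backward(gy)))
        )

    @property
    def n_weighted_layers(self) -> int:
        return 2


# ---------------------------------------------------------------------------
# recurrence


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Module):
    """Single-direction LSTM over (B, T, C); gate order [input, forget, cell, output]."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator | None = None, name: str = "lstm"):
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.Wx = Param(f"{name}.Wx", _uniform_init(rng, (in_dim, 4 * hidden), hidden))
        self.Wh = Param(f"{name}.Wh", _uniform_init(rng, (hidden, 4 * hidden), hidden))
        self.b = Param(f"{name}.b", np.zeros(4 * hidden), is_bias=True)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] == 0:
            raise ValueError(f"LSTM expects a nonempty (B, T, C) sequence, got shape {x.shape}")
        b, t, _ = x.shape
        h = np.zeros((b, self.hidden))
        c = np.zeros((b, self.hidden))
        hh = self.hidden
        caches = []
        out = np.empty((b, t, hh))
        for step in range(t):
            xt = x[:, step]
            z = xt @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :hh])
            f = _sigmoid(z[:, hh : 2 * hh])
            g = np.tanh(z[:, 2 * hh : 3 * hh])
            o = _sigmoid(z[:, 3 * hh :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, step] = h
            caches.append((xt, h_prev, c_prev, i, f, g, o, tc))
        self._caches = caches
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, t, hh = gy.shape
        dx = np.empty((b, t, self.Wx.value.shape[0]))
        dh_next = np.zeros((b, hh))
        dc_next = np.zeros((b, hh))
        for step in reversed(range(t)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._caches[step]
            dh = gy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class BiLSTM(Module):
    """Forward and backward LSTM passes concatenated channel-wise: (B, T, 2H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator | None = None, name: str = "bilstm"):
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(in_dim, hidden, rng, f"{name}.fwd")
        self.bwd = LSTM(in_dim, hidden, rng, f"{name}.bwd")
        self.hidden = hidden

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        hh = self.hidden
        gx_f = self.fwd.backward(gy[:, :, :hh])
        gx_b = self.bwd.backward(gy[:, ::-1, hh:])[:, ::-1]
        return gx_f + gx_b


def bilstm_forward(feature_sequence: np.ndarray, hidden: int, seed: int = 0) -> np.ndarray:
    """Run a freshly seeded BiLSTM over a (T, F) or (B, T, F) sequence.

    Output keeps the input's step count with 2 * hidden channels.
    """
    x = np.asarray(feature_sequence, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.shape[1] == 0:
        raise ValueError("feature sequence is empty")
    net = BiLSTM(x.shape[2], hidden, np.random.default_rng(seed))
    y = net.forward(x)
    return y[0] if squeeze else y


# ---------------------------------------------------------------------------
# classification head and optimiser


def softmax(z: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Scaled softmax sigma(z)_i = exp(beta z_i) / sum_j exp(beta z_j).

    Computed with max-subtraction so large logits cannot overflow.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    zb = beta * z
    zb = zb - zb.max(axis=-1, keepdims=True)
    e = np.exp(zb)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    """Beta-scaled softmax with summed cross-entropy loss over the batch."""

    def __init__(self, beta: float = 1.0):
        self.beta = beta

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
        probs = softmax(logits, self.beta)
        n = logits.shape[0]
        eps = 1e-300
        loss = float(-np.log(probs[np.arange(n), labels] + eps).sum())
        self._cache = (probs, labels)
        return loss, probs

    def backward(self) -> np.ndarray:
        probs, labels = self._cache
        g = probs.copy()
        g[np.arange(len(labels)), labels] -= 1.0
        return self.beta * g


def sgd_step(
    param: np.ndarray,
    grad: np.ndarray,
    prev_delta: np.ndarray,
    learning_rate: float,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
    r: int = 1,
    batch_size: int = 1,
    is_bias: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One SGD-with-momentum update; returns (new_param, new_delta).

    ``grad`` is the batch-summed cost gradient.  Weight decay is scaled by
    the training-set size ``r`` and applied to weights only.
    """
    param = np.asarray(param, dtype=float)
    grad = np.asarray(grad, dtype=float)
    prev_delta = np.asarray(prev_delta, dtype=float)
    if not (param.shape == grad.shape == prev_delta.shape):
        raise ValueError(
            f"shape mismatch: param {param.shape}, grad {grad.shape}, "
            f"prev_delta {prev_delta.shape}"
        )
    delta = -(learning_rate / batch_size) * grad + momentum * prev_delta
    if not is_bias and weight_decay > 0:
        delta = delta - (learning_rate * weight_decay / r) * param
    return param + delta, delta
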