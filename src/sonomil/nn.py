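"""Layers and optimization for the MIL network, built on :mod:`sonomil.autodiff`.

Everything here is plain NumPy: 2-D convolution is an im2col matrix product,
spatial max-pooling is a reshape-and-argmax, and Adam follows the standard
bias-corrected update.  Shapes use the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor, make_op

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "max_pool2x2",
    "global_avg_pool",
    "global_max_pool",
    "softmax",
    "bce_with_logits",
    "Adam",
]


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: recursively collects parameters from attributes."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for parameters: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype).copy()


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Linear(Module):
    """Affine map x @ W + b with W of shape (in_features, out_features)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = Parameter(he_init(rng, (in_features, out_features), in_features, dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


def _im2col(x: np.ndarray, k: int, padding: int, stride: int):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, Ho', Wo', k, k)
    if stride > 1:
        windows = windows[:, :, ::stride, ::stride]
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return cols, ho, wo, x.shape


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding: int,
           stride: int = 1) -> Tensor:
    """2-D cross-correlation via im2col; weight shape (out_ch, in_ch, k, k)."""
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    out_ch, in_ch, k, _ = wd.shape
    cols, ho, wo, padded_shape = _im2col(xd, k, padding, stride)
    out = cols @ wd.reshape(out_ch, -1).T + bias.data
    out = out.reshape(n, ho, wo, out_ch).transpose(0, 3, 1, 2)

    def backward(g):
        gout = g.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        g_w = (gout.T @ cols).reshape(wd.shape)
        g_b = gout.sum(axis=0)
        gcols = (gout @ wd.reshape(out_ch, -1)).reshape(n, ho, wo, in_ch, k, k)
        g_xp = np.zeros(padded_shape, dtype=xd.dtype)
        for ki in range(k):
            for kj in range(k):
                g_xp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += \
                    gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        if padding:
            g_x = g_xp[:, :, padding:padding + h, padding:padding + w]
        else:
            g_x = g_xp
        return g_x, g_w, g_b

    return make_op(out, (x, weight, bias), backward)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 stride: int = 1, dtype=np.float32):
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Parameter(
            he_init(rng, (out_ch, in_ch, kernel_size, kernel_size), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))
        self.padding = kernel_size // 2 if padding is None else padding
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding, self.stride)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pooling; spatial dimensions must be even.

    The backward pass splits the gradient evenly across tied maxima within a
    window (ties essentially only occur at ReLU zeros).
    """
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial size, got {h}x{w}")
    xd = x.data
    quads = (xd[:, :, 0::2, 0::2], xd[:, :, 0::2, 1::2],
             xd[:, :, 1::2, 0::2], xd[:, :, 1::2, 1::2])
    out = np.maximum(np.maximum(quads[0], quads[1]),
                     np.maximum(quads[2], quads[3]))

    def backward(g):
        masks = [q == out for q in quads]
        count = masks[0].astype(xd.dtype)
        for m in masks[1:]:
            count += m
        share = g / count
        gx = np.zeros_like(xd)
        gx[:, :, 0::2, 0::2] = np.where(masks[0], share, 0)
        gx[:, :, 0::2, 1::2] = np.where(masks[1], share, 0)
        gx[:, :, 1::2, 0::2] = np.where(masks[2], share, 0)
        gx[:, :, 1::2, 1::2] = np.where(masks[3], share, 0)
        return (gx,)

    return make_op(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial max."""
    return x.max(axis=(2, 3))


def softmax(scores: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable softmax (max-subtraction before exponentiation)."""
    shifted = scores - scores.data.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logit: Tensor, label: float) -> Tensor:
    """Binary cross-entropy of sigmoid(logit) against a {0,1} label.

    Forward uses the max(z,0) - z*y + log(1 + exp(-|z|)) form, which never
    exponentiates a large positive argument; backward is the exact
    d/dz = sigmoid(z) - y.
    """
    z = logit.data
    y = float(label)
    value = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    sig = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return make_op(value, (logit,), lambda g: (g * (sig - y),))


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("lr must be nonnegative")
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
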