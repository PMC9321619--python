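"""Minimal NumPy layer stack with reverse-mode gradients.

The network in this package is small (well under a million parameters) and
runs on CPU, so the layers are implemented directly on NumPy arrays with
explicit forward/backward passes instead of pulling in a deep-learning
framework. Every layer follows the same functional contract:

    y, cache = layer.forward(x, training=..., rng=...)
    dx       = layer.backward(dy, cache)        # accumulates param.grad

``backward`` *adds* into each parameter's ``.grad`` buffer, so calling a
layer twice in one forward pass (the two Siamese branches share every layer
object) accumulates both contributions — weight sharing falls out of the
calling convention rather than any copying.

Array layout is channels-last: feature maps are ``(batch, height, width,
channels)`` with video frames on the batch axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2D",
    "Dense",
    "LeakyReLU",
    "MaxPool2",
    "ChannelAttention",
    "SpatialAttention",
    "Dropout",
    "Adam",
    "sigmoid",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape})"


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: tracks parameters; subclasses define forward/backward."""

    def params(self) -> list[Param]:
        return []


class LeakyReLU(Layer):
    """Elementwise x for x >= 0, alpha * x otherwise (alpha = 0.01 by default)."""

    def __init__(self, alpha: float = 0.01):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = alpha

    def forward(self, x, *, training=False, rng=None):
        y = np.where(x >= 0, x, self.alpha * x)
        return y, x >= 0

    def backward(self, dy, cache):
        return np.where(cache, dy, self.alpha * dy)


def leaky_relu(x, alpha: float = 0.01):
    """Functional leaky ReLU on a scalar or array."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, alpha * x)
    return out if out.ndim else out.item()


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding k x k patches with 'same' zero padding.

    Returns ``(B, H, W, k, k, C)`` so a reshape to ``(B*H*W, k*k*C)`` matches
    a kernel stored as ``(k, k, C_in, C_out)`` reshaped to ``(k*k*C, C_out)``.
    """
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,H,W,C,k,k
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


class Conv2D(Layer):
    """2-D convolution with 'same' zero padding, stride 1, channels-last.

    ``need_input_grad=False`` lets the first layer of a network skip the
    (useless) gradient with respect to the raw input frames.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv", need_input_grad: bool = True):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        fan_in = kernel * kernel * c_in
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.need_input_grad = need_input_grad
        self.w = Param(f"{name}.w",
                       _glorot_uniform(rng, (kernel, kernel, c_in, c_out), fan_in, c_out))
        self.b = Param(f"{name}.b", np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, *, training=False, rng=None):
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        cols = _im2col(x, self.kernel)  # B,H,W,k,k,C
        flat = cols.reshape(B * H * W, -1)
        wm = self.w.value.reshape(-1, self.c_out)
        y = (flat @ wm + self.b.value).reshape(B, H, W, self.c_out)
        return y, (flat, x.shape)

    def backward(self, dy, cache):
        flat, xshape = cache
        B, H, W, C = xshape
        dyf = dy.reshape(B * H * W, self.c_out)
        self.w.grad += (flat.T @ dyf).reshape(self.w.value.shape)
        self.b.grad += dyf.sum(axis=0)
        if not self.need_input_grad:
            return None
        # input gradient of a same-padded stride-1 conv is the same-padded
        # conv of dy with the spatially flipped, channel-transposed kernel
        w_rot = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)  # k,k,Cout,Cin
        dy_cols = _im2col(np.ascontiguousarray(dy), self.kernel)
        dx = dy_cols.reshape(B * H * W, -1) @ w_rot.reshape(-1, C)
        return dx.reshape(B, H, W, C)


class Dense(Layer):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.n_in, self.n_out = n_in, n_out
        self.w = Param(f"{name}.w", _glorot_uniform(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(f"{name}.b", np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, *, training=False, rng=None):
        return x @ self.w.value + self.b.value, x

    def backward(self, dy, cache):
        x = cache
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class MaxPool2(Layer):
    """Non-overlapping 2x2 max pooling; trailing odd rows/columns are dropped."""

    def forward(self, x, *, training=False, rng=None):
        B, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        xr = x[:, : H2 * 2, : W2 * 2, :].reshape(B, H2, 2, W2, 2, C)
        y = xr.max(axis=(2, 4))
        mask = xr == y[:, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4), keepdims=True)
        return y, (mask, cnt, x.shape)

    def backward(self, dy, cache):
        mask, cnt, xshape = cache
        B, H, W, C = xshape
        H2, W2 = H // 2, W // 2
        dxr = mask / cnt * dy[:, :, None, :, None, :]
        dx = np.zeros(xshape)
        dx[:, : H2 * 2, : W2 * 2, :] = dxr.reshape(B, H2 * 2, W2 * 2, C)
        return dx


class ChannelAttention(Layer):
    """Per-channel sigmoid gates from pooled spatial descriptors.

    Average- and max-pooled channel descriptors pass through one shared
    two-layer bottleneck (reduction ratio r); the two outputs are summed and
    squashed by a sigmoid, giving one multiplicative gate per channel,
    strictly inside (0, 1).
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator,
                 alpha: float = 0.01, name: str = "ca"):
        if ratio < 1:
            raise ValueError(f"reduction ratio must be >= 1, got {ratio}")
        hidden = max(1, channels // ratio)
        self.channels, self.hidden, self.alpha = channels, hidden, alpha
        self.w1 = Param(f"{name}.w1", _glorot_uniform(rng, (channels, hidden), channels, hidden))
        self.b1 = Param(f"{name}.b1", np.zeros(hidden))
        self.w2 = Param(f"{name}.w2", _glorot_uniform(rng, (hidden, channels), hidden, channels))
        self.b2 = Param(f"{name}.b2", np.zeros(channels))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def _mlp(self, d):
        h_pre = d @ self.w1.value + self.b1.value
        h = np.where(h_pre >= 0, h_pre, self.alpha * h_pre)
        return h_pre, h, h @ self.w2.value + self.b2.value

    def _mlp_back(self, dz, d, h_pre, h):
        self.w2.grad += h.T @ dz
        self.b2.grad += dz.sum(axis=0)
        dh = dz @ self.w2.value.T
        dh_pre = np.where(h_pre >= 0, dh, self.alpha * dh)
        self.w1.grad += d.T @ dh_pre
        self.b1.grad += dh_pre.sum(axis=0)
        return dh_pre @ self.w1.value.T

    def gates(self, x):
        """Channel gate vector(s) for a feature map, without applying them."""
        g, _ = self._gates_cached(x)
        return g

    def _gates_cached(self, x):
        avg = x.mean(axis=(1, 2))
        mx = x.max(axis=(1, 2))
        mask = x == mx[:, None, None, :]
        cnt = mask.sum(axis=(1, 2), keepdims=True)
        ha_pre, ha, za = self._mlp(avg)
        hm_pre, hm, zm = self._mlp(mx)
        s = sigmoid(za + zm)
        return s, (avg, mx, mask, cnt, ha_pre, ha, hm_pre, hm, s)

    def forward(self, x, *, training=False, rng=None):
        s, inner = self._gates_cached(x)
        return x * s[:, None, None, :], (x, inner)

    def backward(self, dy, cache):
        x, (avg, mx, mask, cnt, ha_pre, ha, hm_pre, hm, s) = cache
        B, H, W, C = x.shape
        ds = (dy * x).sum(axis=(1, 2))
        dx = dy * s[:, None, None, :]
        dz = ds * s * (1.0 - s)
        davg = self._mlp_back(dz, avg, ha_pre, ha)
        dmx = self._mlp_back(dz, mx, hm_pre, hm)
        dx += davg[:, None, None, :] / (H * W)
        dx += mask / cnt * dmx[:, None, None, :]
        return dx


class SpatialAttention(Layer):
    """Per-location sigmoid gates from channel-pooled maps.

    The channel-wise mean and max maps are stacked as a two-channel image,
    convolved with a single odd-sized kernel (7x7 by default), and squashed
    by a sigmoid into an (H, W) gate applied to every channel.
    """

    def __init__(self, kernel: int, rng: np.random.Generator, name: str = "sa"):
        if kernel % 2 != 1:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = Conv2D(2, 1, kernel, rng, name=f"{name}.conv")

    def params(self):
        return self.conv.params()

    def gates(self, x):
        g, _ = self._gates_cached(x)
        return g

    def _gates_cached(self, x):
        mean_map = x.mean(axis=3)
        max_map = x.max(axis=3)
        mask = x == max_map[..., None]
        cnt = mask.sum(axis=3, keepdims=True)
        stacked = np.stack([mean_map, max_map], axis=-1)
        z, conv_cache = self.conv.forward(stacked)
        s = sigmoid(z[..., 0])
        return s, (mask, cnt, conv_cache, s)

    def forward(self, x, *, training=False, rng=None):
        s, inner = self._gates_cached(x)
        return x * s[..., None], (x, inner)

    def backward(self, dy, cache):
        x, (mask, cnt, conv_cache, s) = cache
        C = x.shape[3]
        ds = (dy * x).sum(axis=3)
        dx = dy * s[..., None]
        dz = (ds * s * (1.0 - s))[..., None]
        dstacked = self.conv.backward(dz, conv_cache)
        dx += dstacked[..., 0:1] / C
        dx += mask / cnt * dstacked[..., 1:2]
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            return x, None
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask, mask

    def backward(self, dy, cache):
        return dy if cache is None else dy * cache


class Adam:
    """Adam optimizer over a fixed parameter list.

    Defaults follow the training recipe used throughout this package:
    learning rate 1e-4, beta1 0.9, beta2 0.999.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
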