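"""Minimal numpy neural-network engine for temporal convolutional networks.

Every layer implements ``forward`` (caching what its backward pass needs)
and ``backward`` (returning the gradient with respect to its input while
accumulating parameter gradients in place).  The engine is deliberately
small: it supports exactly the layers the heartbeat classifier uses —
dilated causal 1D convolution, channel-wise layer normalization, spatial
(channel) dropout, ReLU, a 1x1 skip projection and a dense head — plus
softmax cross-entropy and the Adam optimizer.

Array layout is ``(batch, channels, time)`` throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "CausalConv1d",
    "ChannelLayerNorm",
    "SpatialDropout",
    "ReLU",
    "Dense",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class Param:
    """A learnable array together with its accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name!r}, shape={self.value.shape})"


class Layer:
    """Base class: stateless unless it owns :class:`Param` objects."""

    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def causal_pad(x: np.ndarray, k: int, d: int) -> np.ndarray:
    """Left-pad ``x`` with ``(k - 1) * d`` zeros along the time axis.

    The padding keeps a convolution with ``k`` taps and dilation ``d``
    causal while preserving sequence length; original samples end up
    right-aligned and unchanged.
    """
    if k < 1 or d < 1:
        raise ValueError(f"kernel size and dilation must be >= 1, got k={k}, d={d}")
    x = np.asarray(x, dtype=np.float64)
    pad = (k - 1) * d
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 1) + [(pad, 0)]
    return np.pad(x, width)


class CausalConv1d(Layer):
    """Dilated causal 1D convolution.

    Output at time ``t`` is ``sum_j W[:, :, j] @ x(t - d * j) + b`` with
    taps indexed ``j = 0 .. k-1``; with internal causal padding the output
    has the same length as the input and never looks ahead of ``t``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, *, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if min(in_channels, out_channels, kernel_size, dilation) < 1:
            raise ValueError("conv hyperparameters must be positive integers")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size))
        self.W = Param(f"{name}.W", w)
        self.b = Param(f"{name}.b", np.zeros(out_channels))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (batch, {self.in_channels}, time) input, got shape {x.shape}")
        k, d = self.kernel_size, self.dilation
        n = x.shape[2]
        xp = causal_pad(x, k, d)
        pad = (k - 1) * d
        y = np.empty((x.shape[0], self.out_channels, n))
        y[...] = self.b.value[:, None]
        for j in range(k):
            lo = pad - d * j
            y += np.einsum("oi,bit->bot", self.W.value[:, :, j], xp[:, :, lo:lo + n],
                           optimize=True)
        self._xp = xp
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._xp
        k, d = self.kernel_size, self.dilation
        pad = (k - 1) * d
        n = gy.shape[2]
        gxp = np.zeros_like(xp)
        for j in range(k):
            lo = pad - d * j
            self.W.grad[:, :, j] += np.einsum("bot,bit->oi", gy, xp[:, :, lo:lo + n],
                                              optimize=True)
            gxp[:, :, lo:lo + n] += np.einsum("oi,bot->bit", self.W.value[:, :, j], gy,
                                              optimize=True)
        self.b.grad += gy.sum(axis=(0, 2))
        return gxp[:, :, pad:] if pad else gxp


class ChannelLayerNorm(Layer):
    """Layer normalization across channels, per sample and per time step.

    Statistics are taken over the channel axis only; learnable per-channel
    scale (gamma) and offset (beta) give ``2 * channels`` parameters.
    """

    def __init__(self, channels: int, eps: float = 1e-5, *, name: str = "norm"):
        self.channels = channels
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        g = gy * self.gamma.value[:, None]
        m1 = g.mean(axis=1, keepdims=True)
        m2 = (g * xhat).mean(axis=1, keepdims=True)
        return inv * (g - m1 - xhat * m2)


class SpatialDropout(Layer):
    """Dropout of whole feature channels (per sample) with rate ``p``.

    Identity in inference mode; in training, surviving channels are scaled
    by ``1 / (1 - p)`` so the expected activation is unchanged.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = self.rng.random((x.shape[0], x.shape[1], 1)) >= self.p
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._pos


class Dense(Layer):
    """Fully connected layer on flat feature vectors ``(batch, features)``."""

    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.W = Param(f"{name}.W", rng.uniform(-limit, limit, (in_features, out_features)))
        self.b = Param(f"{name}.b", np.zeros(out_features))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ gy
        self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y_index: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``y_index`` holds integer class indices (not one-hot).
    """
    p = softmax(logits, axis=1)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y_index] + eps).mean()
    g = p.copy()
    g[np.arange(n), y_index] -= 1.0
    return float(loss), g / n


class Adam:
    """Adam optimizer over a list of :class:`Param` objects."""

    def __init__(self, params: list[Param], lr: float = 0.0025,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
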