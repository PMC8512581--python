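"""Minimal feed-forward network engine used by the reference models.

Layers implement ``forward``/``backward`` with explicit caches, parameters
are plain numpy arrays, and the optimizer is SGD with classical momentum.
Everything is single-threaded numpy, so runs are bit-reproducible for a
fixed seed.  Convolutions use im2col with stride 1 and either "same"
(default) or "valid" padding; inputs are float32 images in [0, 1] with
layout (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "Dropout",
    "Flatten",
    "Linear",
    "Network",
    "SGD",
]


class Layer:
    """Base layer: stateless unless it has parameters or a forward cache."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def init_params(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N, C, H, W) already padded; returns (N, H_out*W_out, C*kh*kw)
    n, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, ho, wo, kh, kw), strides=(s0, s1, s2, s3, s2, s3)
    )
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)


class Conv2d(Layer):
    """3x3 (or any odd-kernel) convolution, stride 1."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ValueError(f"padding must be 'same' or 'valid', got {padding!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.W = np.zeros((out_channels, in_channels, kernel_size, kernel_size), np.float32)
        self.b = np.zeros(out_channels, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        # uniform fan-in scaling: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
        fan_in = self.in_channels * self.kernel_size ** 2
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, self.W.shape).astype(np.float32)
        self.b = rng.uniform(-bound, bound, self.b.shape).astype(np.float32)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        k = self.kernel_size
        pad = (k - 1) // 2 if self.padding == "same" else 0
        if pad:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        else:
            xp = x
        n = x.shape[0]
        ho, wo = xp.shape[2] - k + 1, xp.shape[3] - k + 1
        cols = _im2col(xp, k, k)  # (N, ho*wo, C*k*k)
        wmat = self.W.reshape(self.out_channels, -1)  # (O, C*k*k)
        out = cols @ wmat.T + self.b  # (N, ho*wo, O)
        self._cache = (cols, x.shape, pad, ho, wo)
        return out.transpose(0, 2, 1).reshape(n, self.out_channels, ho, wo)

    def backward(self, grad_out):
        cols, x_shape, pad, ho, wo = self._cache
        n, c, h, w = x_shape
        k = self.kernel_size
        g = grad_out.reshape(n, self.out_channels, ho * wo).transpose(0, 2, 1)  # (N, P, O)
        wmat = self.W.reshape(self.out_channels, -1)
        self.dW[...] = np.tensordot(g, cols, axes=([0, 1], [0, 1])).reshape(self.W.shape)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ wmat  # (N, P, C*k*k)
        # col2im: scatter-add patches back onto the padded input
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), np.float32)
        dcols = dcols.reshape(n, ho, wo, c, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out):
        return grad_out * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling; input spatial dims must be divisible by
    the pool size."""

    def __init__(self, pool_size: int = 2):
        self.pool_size = pool_size
        self._cache = None

    def forward(self, x, training, rng):
        p = self.pool_size
        n, c, h, w = x.shape
        if h % p or w % p:
            raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {p}")
        xr = x.reshape(n, c, h // p, p, w // p, p)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties toward the first max so the backward pass routes each
        # output gradient to exactly one input
        cum = np.cumsum(mask.reshape(n, c, h // p, w // p, p * p), axis=-1)
        first = (cum == 1) & mask.reshape(n, c, h // p, w // p, p * p)
        self._cache = (first, x.shape)
        return out

    def backward(self, grad_out):
        first, x_shape = self._cache
        p = self.pool_size
        n, c, h, w = x_shape
        g = first * grad_out[:, :, :, :, None]
        return (
            g.reshape(n, c, h // p, w // p, p, p)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float = 0.5):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must lie in [0, 1), got {p}")
        self.p = p
        self._mask = None

    def forward(self, x, training, rng):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad_out):
        if self._mask is None:
            return grad_out
        return grad_out * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int):
        self.in_features = in_features
        self.out_features = out_features
        self.W = np.zeros((out_features, in_features), np.float32)
        self.b = np.zeros(out_features, np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def init_params(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_features)
        self.W = rng.uniform(-bound, bound, self.W.shape).astype(np.float32)
        self.b = rng.uniform(-bound, bound, self.b.shape).astype(np.float32)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out):
        self.dW[...] = grad_out.T @ self._x
        self.db[...] = grad_out.sum(axis=0)
        return grad_out @ self.W


class Network:
    """A sequential stack of layers producing per-class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init_params(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init_params(rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    __call__ = forward

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = grad_logits.astype(np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state does not match network parameters")
        for p, s in zip(own, state):
            if p.shape != s.shape:
                raise ValueError(f"parameter shape mismatch: {p.shape} vs {s.shape}")
            p[...] = s


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, network: Network, learning_rate: float, momentum: float = 0.0):
        if learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if momentum < 0:
            raise ValueError("momentum must be nonnegative")
        self.network = network
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in network.params()]

    def step(self) -> None:
        for p, g, v in zip(self.network.params(), self.network.grads(), self.velocity):
            if self.momentum:
                v *= self.momentum
                v += g
                p -= self.learning_rate * v
            else:
                p -= self.learning_rate * g
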