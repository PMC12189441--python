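"""Minimal feed-forward neural-network layer used by the fusion classifiers.

Implements exactly the pieces the concatenated image+tabular architecture
needs -- 3x3 valid convolutions (im2col), 2x2 max pooling, global average
pooling, dense layers, inverted dropout, ReLU, a two-logit softmax head and
the Adam optimizer -- all in NumPy with explicit forward/backward passes.
Weights are initialized with He fans from a caller-supplied RNG so every
training run is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "ReLU",
    "Dropout",
    "Conv2D",
    "MaxPool2",
    "GlobalAvgPool",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_from_logits",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - np.max(logits, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy_from_logits(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n
    grad = (p - onehot) / n
    return float(loss), grad


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W, self.b]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def params(self):
        return []


class Conv2D:
    """3x3 valid convolution on NHWC tensors via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, ksize: int = 3):
        self.k = ksize
        fan_in = ksize * ksize * c_in
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._cols = None
        self._xshape = None

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        k = self.k
        windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # windows: (n, oh, ow, c, k, k) -> cols (n*oh*ow, k*k*c)
        oh, ow = h - k + 1, w - k + 1
        cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, k * k * c)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.W.value + self.b.value
        return out.reshape(n, oh, ow, -1)

    def backward(self, grad):
        n, h, w, c = self._xshape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        g = grad.reshape(n * oh * ow, -1)
        self.W.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        gcols = (g @ self.W.value.T).reshape(n, oh, ow, k, k, c)
        dx = np.zeros(self._xshape)
        for di in range(k):
            for dj in range(k):
                dx[:, di:di + oh, dj:dj + ow, :] += gcols[:, :, :, di, dj, :]
        return dx

    def params(self):
        return [self.W, self.b]


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def __init__(self):
        self._mask = None
        self._xshape = None

    def forward(self, x, train=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :]
        blocks = xc.reshape(n, h2, 2, w2, 2, c)
        out = blocks.max(axis=(2, 4))
        self._mask = blocks == out[:, :, None, :, None, :]
        self._xshape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[:, :, None, :, None, :]
        # split ties evenly so gradient mass is conserved
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = g / counts
        dx = np.zeros(self._xshape)
        dx[:, : h2 * 2, : w2 * 2, :] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx

    def params(self):
        return []


class GlobalAvgPool:
    def __init__(self):
        self._xshape = None

    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._xshape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._xshape).copy()

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
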