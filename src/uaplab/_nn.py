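"""Minimal NumPy neural-network core with exact manual backpropagation.

Layers operate on NHWC float64 arrays. Everything is deterministic given
the seeds fed to the initializers and the training loop, which is what the
attack loops and the reproducibility contracts rely on. Only the pieces the
package needs are implemented: 3x3 convolutions, ReLU, 2x2 max-pooling,
dense layers, softmax cross-entropy, and SGD with momentum and step decay.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    hp, wp = x.shape[1], x.shape[2]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, ho, wo, kh, kw, c),
        strides=(s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]),
    )
    return np.ascontiguousarray(view).reshape(n * ho * wo, kh * kw * c), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, h, w, c = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dx = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    dcols = dcols.reshape(n, ho, wo, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += dcols[:, :, :, i, j, :]
    if pad:
        dx = dx[:, pad : hp - pad, pad : wp - pad, :]
    return dx


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2d(Layer):
    """3x3-style convolution, stride 1, 'same' padding by default."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = ksize * ksize * in_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.pad = pad
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        cols, ho, wo = _im2col(x, self.ksize, self.ksize, 1, self.pad)
        y = cols @ self.w + self.b
        self._cache = (x.shape, cols)
        return y.reshape(x.shape[0], ho, wo, self.out_ch)

    def backward(self, dout):
        x_shape, cols = self._cache
        dflat = dout.reshape(-1, self.out_ch)
        self.dw[...] = cols.T @ dflat
        self.db[...] = dflat.sum(axis=0)
        dcols = dflat @ self.w.T
        return _col2im(dcols, x_shape, self.ksize, self.ksize, 1, self.pad)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient routed to the first argmax on ties."""

    def forward(self, x):
        n, h, w, c = x.shape
        xw = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._idx = xw.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(xw, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, h, w, c = self._x_shape
        dxw = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dxw, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dxw.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def copy(self) -> "Sequential":
        import copy as _copy

        return _copy.deepcopy(self)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-300
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class SGD:
    """SGD with classical momentum and step learning-rate decay."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.05, momentum: float = 0.9,
                 decay_every: int = 0, decay_factor: float = 0.5):
        self.params = params
        self.velocity = [np.zeros_like(p) for p in params]
        self.base_lr = lr
        self.momentum = momentum
        self.decay_every = decay_every
        self.decay_factor = decay_factor
        self.lr = lr

    def set_epoch(self, epoch: int) -> None:
        if self.decay_every > 0:
            self.lr = self.base_lr * self.decay_factor ** (epoch // self.decay_every)
        else:
            self.lr = self.base_lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, v, g in zip(self.params, self.velocity, grads):
            v *= self.momentum
            v -= self.lr * g
            p += v
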