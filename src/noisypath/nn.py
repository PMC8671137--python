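"""Minimal CPU neural-network layers with manual backpropagation.

Everything downstream (patch classifier, context autoencoder, smoothing-weight
head) is built from these pieces. Arrays are float32 NCHW. Each layer exposes
``forward``/``backward`` and a list of ``Param`` slots; :class:`Adam` updates
them in place. Determinism is exact: given seeded initialisation and a fixed
batch order, two runs produce bit-identical weights on the same machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "Center",
    "Flatten",
    "Upsample2x",
    "AvgPool2d",
    "Sequential",
    "Adam",
    "sigmoid",
    "save_model",
    "load_model",
]


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, L) patch matrix, L = Ho*Wo."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)


def _col2im(cols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols6[
                :, :, i, j
            ]
    if pad:
        xp = xp[:, :, pad : pad + h, pad : pad + w]
    return xp


class Conv2d(Layer):
    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.w = Param(w.astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.stride, self.pad)
        wm = self.w.value.reshape(self.w.value.shape[0], -1)
        out = np.matmul(wm[None], cols) + self.b.value[None, :, None]
        ho = (h + 2 * self.pad - self.k) // self.stride + 1
        wo = (w + 2 * self.pad - self.k) // self.stride + 1
        self._cache = (x.shape, cols)
        return out.reshape(n, -1, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xshape, cols = self._cache
        n = dout.shape[0]
        dflat = dout.reshape(n, dout.shape[1], -1)
        wm = self.w.value.reshape(self.w.value.shape[0], -1)
        self.w.grad += (
            np.einsum("ncl,nkl->ck", dflat, cols).reshape(self.w.value.shape)
        )
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(wm.T[None], dflat)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nin, nout))
        self.w = Param(w.astype(np.float32))
        self.b = Param(np.zeros(nout, dtype=np.float32))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x).astype(x.dtype)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class Center(Layer):
    """Subtract a fixed offset (input centering; no learnable state)."""

    def __init__(self, offset: float = 0.5):
        self.offset = offset

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x - self.offset

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling (used by the decoder)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class AvgPool2d(Layer):
    """Non-overlapping average pooling with square window."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        return dout.repeat(k, axis=2).repeat(k, axis=3) / (k * k)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


class Adam:
    """Adaptive-moment optimizer (the training optimizer throughout)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                p.value.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def save_model(model: Sequential, path: str, meta: dict | None = None) -> None:
    """Serialize parameters to .npz with a JSON sidecar recording metadata."""
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(path, **arrays)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(meta or {}, fh, indent=2, default=str)


def load_model(model: Sequential, path: str) -> Sequential:
    """Load parameters saved by :func:`save_model` into a same-shape model."""
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    for i, p in enumerate(model.params()):
        arr = data[f"p{i}"]
        if arr.shape != p.value.shape:
            raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.value.shape}")
        p.value[...] = arr
    return model
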