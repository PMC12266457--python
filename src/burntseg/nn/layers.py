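"""Layer primitives with explicit backpropagation.

All layers take channels-last inputs ``(N, H, W, C)`` (the GRU takes
``(N, L, D)`` sequences). Each layer caches what its backward pass needs
only when ``train=True``; evaluation passes keep no caches so full-size
forward passes stay memory-bounded.

Weight initialization is He-normal (std = sqrt(2 / fan_in)) from an
explicitly seeded generator, so builds are reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(dtype)


class Conv2D(Layer):
    """k x k convolution, stride 1, zero 'same' padding, optional ReLU fused off."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, dtype=np.float32,
                 name: str = "conv"):
        rng = rng or np.random.default_rng()
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = Param(_he_normal(rng, (k * k * cin, cout), k * k * cin, dtype),
                       f"{name}.W")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        n, h, w = x.shape[:3]
        return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * self.cin)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        out = self._cols(x) @ self.W.value + self.b.value
        if train:
            self._x = x
        return out.reshape(n, h, w, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, h, w, _ = x.shape
        k = self.k
        p = k // 2
        dflat = dout.reshape(n * h * w, self.cout)
        cols = self._cols(x)
        self.W.grad += cols.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(n, h, w, k, k, self.cin)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=x.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki:ki + h, kj:kj + w, :] += dcols[:, :, :, ki, kj, :]
        self._x = None
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2 x 2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, train: bool = False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == out[:, :, None, :, None, :]
            self._shape = x.shape
        return out

    def backward(self, dout):
        n, h, w, c = self._shape
        d = self._mask * dout[:, :, None, :, None, :]
        # if a window had tied maxima, split the gradient between them
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        d = d / counts
        return d.reshape(n, h, w, c)


class Dropout(Layer):
    """Inverted dropout: active only in training passes."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self.rate == 0.0:
            return dout
        return dout * self._mask.astype(dout.dtype)


class ConvTranspose2x2(Layer):
    """2 x 2 transposed convolution with stride 2 (exact 2x upsampling).

    With kernel equal to stride, output blocks do not overlap:
    ``out[n, 2i+a, 2j+b, o] = sum_c x[n, i, j, c] W[c, a, b, o] + bias``.
    """

    def __init__(self, cin: int, cout: int, rng=None, dtype=np.float32,
                 name: str = "upconv"):
        rng = rng or np.random.default_rng()
        self.cin, self.cout = cin, cout
        self.W = Param(_he_normal(rng, (cin, 2, 2, cout), cin, dtype), f"{name}.W")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train: bool = False):
        n, h, w, _ = x.shape
        out = np.einsum("nijc,cabo->niajbo", x, self.W.value, optimize=True)
        out = out.reshape(n, 2 * h, 2 * w, self.cout) + self.b.value
        if train:
            self._x = x
        return out

    def backward(self, dout):
        x = self._x
        n, h, w, _ = x.shape
        dyr = dout.reshape(n, h, 2, w, 2, self.cout)
        self.W.grad += np.einsum("nijc,niajbo->cabo", x, dyr, optimize=True)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        self._x = None
        return np.einsum("niajbo,cabo->nijc", dyr, self.W.value, optimize=True)


class GRU(Layer):
    """Unidirectional GRU over ``(N, L, D)`` returning the full sequence.

    Gate equations (h_0 = 0):
        z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
        r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
        g_t = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh)
        h_t = z_t * h_{t-1} + (1 - z_t) * g_t
    """

    def __init__(self, d_in: int, units: int, rng=None, dtype=np.float32,
                 name: str = "gru"):
        rng = rng or np.random.default_rng()
        self.d_in, self.units = d_in, units
        def mk(shape, fan, nm):
            return Param(_he_normal(rng, shape, fan, dtype), f"{name}.{nm}")
        self.Wz, self.Wr, self.Wh = (mk((d_in, units), d_in, n) for n in ("Wz", "Wr", "Wh"))
        self.Uz, self.Ur, self.Uh = (mk((units, units), units, n) for n in ("Uz", "Ur", "Uh"))
        self.bz = Param(np.zeros(units, dtype=dtype), f"{name}.bz")
        self.br = Param(np.zeros(units, dtype=dtype), f"{name}.br")
        self.bh = Param(np.zeros(units, dtype=dtype), f"{name}.bh")

    def params(self):
        return [self.Wz, self.Wr, self.Wh, self.Uz, self.Ur, self.Uh,
                self.bz, self.br, self.bh]

    @staticmethod
    def _sigmoid(a):
        out = np.empty_like(a)
        pos = a >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
        e = np.exp(a[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    def forward(self, x, train: bool = False):
        n, L, _ = x.shape
        H = self.units
        h = np.zeros((n, H), dtype=x.dtype)
        out = np.empty((n, L, H), dtype=x.dtype)
        cache = [] if train else None
        for t in range(L):
            xt = x[:, t, :]
            z = self._sigmoid(xt @ self.Wz.value + h @ self.Uz.value + self.bz.value)
            r = self._sigmoid(xt @ self.Wr.value + h @ self.Ur.value + self.br.value)
            rh = r * h
            g = np.tanh(xt @ self.Wh.value + rh @ self.Uh.value + self.bh.value)
            h_new = z * h + (1.0 - z) * g
            out[:, t, :] = h_new
            if train:
                cache.append((xt, h, z, r, rh, g))
            h = h_new
        self._cache = cache
        return out

    def backward(self, dout):
        n, L, H = dout.shape
        dx = np.empty((n, L, self.d_in), dtype=dout.dtype)
        dh = np.zeros((n, H), dtype=dout.dtype)
        for t in range(L - 1, -1, -1):
            xt, h_prev, z, r, rh, g = self._cache[t]
            dh = dh + dout[:, t, :]
            dz = dh * (h_prev - g)
            dg = dh * (1.0 - z)
            dh_prev = dh * z
            da_g = dg * (1.0 - g * g)
            self.Wh.grad += xt.T @ da_g
            self.Uh.grad += rh.T @ da_g
            self.bh.grad += da_g.sum(axis=0)
            drh = da_g @ self.Uh.value.T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            self.Wz.grad += xt.T @ da_z
            self.Uz.grad += h_prev.T @ da_z
            self.bz.grad += da_z.sum(axis=0)
            self.Wr.grad += xt.T @ da_r
            self.Ur.grad += h_prev.T @ da_r
            self.br.grad += da_r.sum(axis=0)
            dx[:, t, :] = da_z @ self.Wz.value.T + da_r @ self.Wr.value.T + da_g @ self.Wh.value.T
            dh = dh_prev + da_z @ self.Uz.value.T + da_r @ self.Ur.value.T
        self._cache = None
        return dx


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    m = logits.max(axis=axis, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=axis, keepdims=True)
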