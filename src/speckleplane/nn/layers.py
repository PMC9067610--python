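"""Layers with forward/backward passes on NCHW float32 arrays."""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) with 'same' zero padding (k odd)."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k) -> (N, C*k*k, H*W)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of _im2col."""
    n, c, h, w = shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, p : p + h, p : p + w] if p else dxp


class Conv2d(Layer):
    """'Same' convolution with odd kernel size; He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        std = np.sqrt(2.0 / (cin * k * k))
        self.k = k
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._xshape = x.shape
        if self.k == 1:
            self._cols = x.reshape(n, c, h * w)
        else:
            self._cols = _im2col(x, self.k)
        out = np.matmul(self.w.value[None], self._cols) + self.b.value[None, :, None]
        return out.reshape(n, self.cout, h, w)

    def backward(self, dy):
        n, _, h, w = self._xshape
        dyf = dy.reshape(n, self.cout, h * w)
        self.w.grad += np.einsum("nof,ncf->oc", dyf, self._cols, optimize=True)
        self.b.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T[None], dyf)
        if self.k == 1:
            return dcols.reshape(self._xshape)
        return _col2im(dcols, self._xshape, self.k)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / nin)
        self.w = Param(rng.normal(0.0, std, size=(nout, nin)))
        self.b = Param(np.zeros(nout))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class MaxPool2(Layer):
    """2x2 max pooling (even spatial sides required)."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial side must be even for 2x2 pooling")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._inshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._arg[..., None], dy[..., None], axis=-1)
        r = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return r.reshape(n, c, h, w)


class Upsample2(Layer):
    """2x2 nearest-neighbor upsampling; backward sums each 2x2 block."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Concat(Layer):
    """Channel concatenation of two inputs (used for U-Net skips)."""

    def forward(self, a, b):
        self._ca = a.shape[1]
        return np.concatenate([a, b], axis=1)

    def backward(self, dy):
        return dy[:, : self._ca], dy[:, self._ca :]
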