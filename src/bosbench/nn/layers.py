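"""Forward/backward layer primitives on float32 NCHW arrays.

Every op caches whatever its backward pass needs during forward; a graph
is executed serially, so a single cache slot per op suffices.  Gradients
of parameters accumulate into ``Param.grad`` and are zeroed by the
optimizer step.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Op:
    """Base class: single-output operation with cached backward."""

    def forward(self, *xs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError  # pragma: no cover

    def params(self) -> list[Param]:
        return []


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, OH*OW) for stride-1 windows."""
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, C, OH, OW, k, k) -> (N, C, k, k, OH, OW)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


class Conv2d(Op):
    """Stride-1 convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, cin: int, cout: int, ksize: int,
                 rng: np.random.Generator):
        if ksize % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(cout, fan_in)).astype(np.float32)
        self.weight = Param(w)
        self.bias = Param(np.zeros(cout, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = (self.k - 1) // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        cols = _im2col(xp, self.k)           # (N, CKK, HW)
        self._cols, self._xshape = cols, x.shape
        y = np.matmul(self.weight.value[None], cols)   # (N, cout, HW)
        y += self.bias.value[None, :, None]
        return y.reshape(n, self.cout, h, w)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, c, h, w = self._xshape
        k, p = self.k, (self.k - 1) // 2
        gyf = gy.reshape(n, self.cout, h * w)
        self.weight.grad += np.matmul(
            gyf, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.bias.grad += gyf.sum(axis=(0, 2))
        gcols = np.matmul(self.weight.value.T[None], gyf)  # (N, CKK, HW)
        gcols = gcols.reshape(n, c, k, k, h, w)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + h, j:j + w] += gcols[:, :, i, j]
        gx = gxp[:, :, p:p + h, p:p + w] if p else gxp
        return (gx,)


class ReLU(Op):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return (np.where(self._mask, gy, 0.0),)


class MaxPool2x2(Op):
    """2x2 max pooling with stride 2 (spatial dims must be even).

    Implemented as a chain of four strided slices; the winner index per
    window (first match, row-major window order) is kept for backward.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        slices = [x[:, :, di::2, dj::2] for di in (0, 1) for dj in (0, 1)]
        y = slices[0].copy()
        for s in slices[1:]:
            np.maximum(y, s, out=y)
        am = np.zeros(y.shape, dtype=np.int8)
        taken = np.zeros(y.shape, dtype=bool)
        for k, s in enumerate(slices):
            hit = ~taken & (s == y)
            am[hit] = k
            taken |= hit
        self._am = am
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        gx = np.zeros(self._xshape, dtype=gy.dtype)
        for k, (di, dj) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
            gx[:, :, di::2, dj::2] = np.where(self._am == k, gy, 0.0)
        return (gx,)


class MaxPool3x3Same(Op):
    """3x3 stride-1 max pooling, 'same' size (the pooling branch)."""

    _OFFSETS = [(di, dj) for di in range(3) for dj in range(3)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xshape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)),
                    constant_values=-np.inf)
        slices = [xp[:, :, di:di + h, dj:dj + w] for di, dj in self._OFFSETS]
        y = slices[0].copy()
        for s in slices[1:]:
            np.maximum(y, s, out=y)
        am = np.zeros(y.shape, dtype=np.int8)
        taken = np.zeros(y.shape, dtype=bool)
        for k, s in enumerate(slices):
            hit = ~taken & (s == y)
            am[hit] = k
            taken |= hit
        self._am = am
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, c, h, w = self._xshape
        gxp = np.zeros((n, c, h + 2, w + 2), dtype=gy.dtype)
        for k, (di, dj) in enumerate(self._OFFSETS):
            gxp[:, :, di:di + h, dj:dj + w] += np.where(self._am == k, gy, 0.0)
        return (gxp[:, :, 1:1 + h, 1:1 + w],)


class MaxPool2x2Same(Op):
    """2x2 stride-1 max pooling, 'same' size (asymmetric pad right/down).

    On binary contour images this is a grayscale dilation that closes
    1-px gaps while thickening strokes by a single pixel.
    """

    _OFFSETS = [(0, 0), (0, 1), (1, 0), (1, 1)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xshape = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)),
                    constant_values=-np.inf)
        slices = [xp[:, :, di:di + h, dj:dj + w] for di, dj in self._OFFSETS]
        y = slices[0].copy()
        for s in slices[1:]:
            np.maximum(y, s, out=y)
        am = np.zeros(y.shape, dtype=np.int8)
        taken = np.zeros(y.shape, dtype=bool)
        for k, s in enumerate(slices):
            hit = ~taken & (s == y)
            am[hit] = k
            taken |= hit
        self._am = am
        return y

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, c, h, w = self._xshape
        gxp = np.zeros((n, c, h + 1, w + 1), dtype=gy.dtype)
        for k, (di, dj) in enumerate(self._OFFSETS):
            gxp[:, :, di:di + h, dj:dj + w] += np.where(self._am == k, gy,
                                                        0.0)
        return (gxp[:, :, :h, :w],)


class GlobalAvgPool(Op):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        n, c, h, w = self._xshape
        g = np.broadcast_to(gy[:, :, None, None] / (h * w),
                            self._xshape)
        return (np.ascontiguousarray(g),)


class Dense(Op):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / din),
                       size=(dout, din)).astype(np.float32)
        self.weight = Param(w)
        self.bias = Param(np.zeros(dout, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return (gy @ self.weight.value,)


class Add(Op):
    """Elementwise sum of two branches (residual merge)."""

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return a + b

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return (gy, gy)


class Concat(Op):
    """Channel-axis concatenation of parallel branches."""

    def forward(self, *xs: np.ndarray) -> np.ndarray:
        self._sizes = [x.shape[1] for x in xs]
        return np.concatenate(xs, axis=1)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        splits = np.cumsum(self._sizes)[:-1]
        return tuple(np.ascontiguousarray(g)
                     for g in np.split(gy, splits, axis=1))


class Flatten(Op):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        return (gy.reshape(self._xshape),)
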