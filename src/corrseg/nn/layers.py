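"""Minimal CNN building blocks on NumPy arrays.

Every layer is a small object with ``forward(x)`` / ``backward(dy)`` and an
explicit parameter list, so the whole network is trainable with plain
hand-derived backpropagation.  Convolutions are stride-1 GEMMs over im2col
patches (float32 throughout); gradients w.r.t. the input are computed as a
second GEMM against the 180°-rotated kernels, which keeps everything inside
BLAS.  Layout is NCHW.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H'*W', C*k*k) patch matrix for a stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    v = v.transpose(0, 2, 3, 1, 4, 5)  # N,H',W',C,k,k
    n, h, w = v.shape[:3]
    return np.ascontiguousarray(v).reshape(n * h * w, -1)


class Conv2d:
    """Stride-1 2-D convolution, kernel size 1 or 3 (3x3 uses 1-px padding)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = 1 if k == 3 else 0
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.w = Param(w)
        self.b = Param(np.zeros(c_out))
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        if self.k == 1:
            xf = x.transpose(0, 2, 3, 1).reshape(-1, self.c_in)
        else:
            xf = _im2col(x, 3, 1)
        y = xf @ self.w.value.T
        y += self.b.value
        self._cols = xf if train else None
        self._shape = x.shape
        return np.ascontiguousarray(
            y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.w.grad += dyf.T @ self._cols
        self.b.grad += dyf.sum(axis=0)
        if self.k == 1:
            dx = dyf @ self.w.value
            return np.ascontiguousarray(
                dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
            )
        # full correlation of dy with the flipped kernels
        wk = self.w.value.reshape(self.c_out, self.c_in, 3, 3)
        wg = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.c_in, -1)
        cols = _im2col(dy.astype(np.float32, copy=False), 3, 1)
        dx = cols @ wg.T
        return np.ascontiguousarray(
            dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        )


class GroupNorm:
    """Group normalization over (C/G, H, W) per sample, with affine scale/shift."""

    def __init__(self, channels: int, max_groups: int = 32):
        self.channels = channels
        self.groups = _largest_divisor(channels, max_groups)
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = 1e-5
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xg - mu) * inv
        xhat = xhat.reshape(n, c, h, w)
        if train:
            self._cache = (xhat, inv)
        return xhat * self.gamma.value[:, None, None] + self.beta.value[:, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, h, w = dy.shape
        g = self.groups
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[:, None, None]).reshape(n, g, -1)
        xh = xhat.reshape(n, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - m1 - xh * m2)
        return dx.reshape(n, c, h, w)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def __init__(self):
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        v = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
        idx = v.argmax(axis=4)
        y = np.take_along_axis(v, idx[..., None], axis=4)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        h2, w2 = h // 2, w // 2
        dv = np.zeros((n, c, h2, w2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, idx[..., None], dy[..., None], axis=4)
        dx = np.zeros((n, c, h, w), dtype=dy.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dv.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, h2 * 2, w2 * 2
            )
        )
        return dx


class NearestResize:
    """Nearest-neighbour resize to an arbitrary (not smaller) spatial target."""

    def __init__(self):
        self._cache = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, th: int, tw: int, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        ri = (np.arange(th) * h) // th
        ci = (np.arange(tw) * w) // tw
        y = x[:, :, ri][:, :, :, ci]
        if train:
            self._cache = (ri, ci, (h, w))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ri, ci, (h, w) = self._cache
        # indices are monotone and surjective (target >= source), so reduceat
        # sums each source pixel's fan-out in one pass per axis
        rstart = np.searchsorted(ri, np.arange(h))
        cstart = np.searchsorted(ci, np.arange(w))
        dx = np.add.reduceat(dy, rstart, axis=2)
        dx = np.add.reduceat(dx, cstart, axis=3)
        return dx


def _largest_divisor(n: int, cap: int) -> int:
    for d in range(min(cap, n), 0, -1):
        if n % d == 0:
            return d
    return 1
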