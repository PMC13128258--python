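"""Minimal volumetric neural-network layers with explicit backprop.

Each layer implements ``forward(x)`` and ``backward(dy)`` on
``(C, nx, ny, nz)`` arrays, caching what the gradient needs.  Parameter
gradients accumulate into ``Param.grad`` until the optimizer clears
them, so a layer can be applied several times per step (weight sharing
across loadings) and the gradients sum correctly.

Convolutions are im2col + BLAS matmul; the input gradient reuses the
same path with a spatially flipped, channel-transposed kernel, and the
weight gradient is a single matmul against the cached column matrix.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv3d", "ReLU", "Softplus", "MaxPool3d", "TrilinearUp3d",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


_COL_INDEX_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _col_index(shape: tuple[int, int, int]) -> np.ndarray:
    """(27, N) flat indices of each 3x3x3 window into the padded volume."""
    if shape not in _COL_INDEX_CACHE:
        nx, ny, nz = shape
        gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.empty((27, nx * ny * nz), dtype=np.int32)
        k = 0
        for dx in range(3):
            for dy in range(3):
                for dz in range(3):
                    off = ((gx + dx) * (ny + 2) + (gy + dy)) * (nz + 2) + (gz + dz)
                    idx[k] = off.ravel()
                    k += 1
        _COL_INDEX_CACHE[shape] = idx
    return _COL_INDEX_CACHE[shape]


class _ColBuffers:
    """Reusable pad/column buffers for one (channels, grid) geometry."""

    def __init__(self, C: int, shape: tuple[int, int, int], dtype):
        nx, ny, nz = shape
        self.shape = shape
        self.n = nx * ny * nz
        self.pad = np.zeros((C, nx + 2, ny + 2, nz + 2), dtype=dtype)

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """(C, nx, ny, nz) -> (C*27, N) with zero same-padding; the
        gather runs through a cached per-shape index table and a reused
        padding buffer."""
        self.pad[:, 1:-1, 1:-1, 1:-1] = x
        flat = self.pad.reshape(self.pad.shape[0], -1)
        cols = np.take(flat, _col_index(self.shape), axis=1)
        return cols.reshape(-1, self.n)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """One-shot column matrix (used by tests); layers keep buffers."""
    buf = _ColBuffers(x.shape[0], x.shape[1:], x.dtype)
    return buf.im2col(x).copy()


class Conv3d:
    """Same-padded 3-D convolution (cross-correlation), kernel 1 or 3."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel ** 3
        scale = np.sqrt(2.0 / fan_in)            # He initialization
        self.W = Param((rng.standard_normal((out_ch, fan_in)) * scale).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._dtype = dtype
        self._shape = None
        self._fwd_buf = None     # _ColBuffers for the input gather
        self._bwd_buf = None     # _ColBuffers for the dy gather
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        if self.kernel == 1:
            self._cols = x.reshape(self.in_ch, -1)
        else:
            if self._fwd_buf is None or self._fwd_buf.shape != x.shape[1:]:
                self._fwd_buf = _ColBuffers(self.in_ch, x.shape[1:], self._dtype)
            self._cols = self._fwd_buf.im2col(x)
        y = self.W.value @ self._cols + self.b.value[:, None]
        return y.reshape((self.out_ch,) + x.shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyf = dy.reshape(self.out_ch, -1)
        self.W.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        if self.kernel == 1:
            dx = self.W.value.T @ dyf
            return dx.reshape(self._shape)
        # input gradient: correlate dy with the flipped, transposed kernel
        Wk = self.W.value.reshape(self.out_ch, self.in_ch, 3, 3, 3)
        Wflip = Wk[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        Wmat = np.ascontiguousarray(Wflip.reshape(self.in_ch, self.out_ch * 27))
        if self._bwd_buf is None or self._bwd_buf.shape != dy.shape[1:]:
            self._bwd_buf = _ColBuffers(self.out_ch, dy.shape[1:], self._dtype)
        dx = Wmat @ self._bwd_buf.im2col(np.ascontiguousarray(dy, self._dtype))
        return dx.reshape(self._shape)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Softplus:
    """Stable softplus y = log(1 + exp(x)); keeps parameter heads positive."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._sig = 1.0 / (1.0 + np.exp(-x))
        return np.logaddexp(0.0, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._sig


class MaxPool3d:
    """2x2x2 max pooling; grid dims must be even."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        C, nx, ny, nz = x.shape
        if nx % 2 or ny % 2 or nz % 2:
            raise ValueError(f"grid {x.shape[1:]} not divisible by 2 for pooling")
        xr = x.reshape(C, nx // 2, 2, ny // 2, 2, nz // 2, 2)
        xw = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, nx // 2, ny // 2, nz // 2, 8)
        self._arg = xw.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xw, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, nx, ny, nz = self._shape
        dxw = np.zeros((C, nx // 2, ny // 2, nz // 2, 8), dtype=dy.dtype)
        np.put_along_axis(dxw, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxw.reshape(C, nx // 2, ny // 2, nz // 2, 2, 2, 2)
        return dxr.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, nx, ny, nz)


def _up_matrix(n: int, dtype) -> np.ndarray:
    """(2n, n) linear interpolation matrix for scale-2 upsampling.

    Output sample i sits at input coordinate i/2 - 1/4 (cell-centered),
    clamped at the edges; the backward pass is the transpose.
    """
    U = np.zeros((2 * n, n), dtype=dtype)
    for i in range(2 * n):
        pos = i / 2.0 - 0.25
        lo = int(np.floor(pos))
        w = pos - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        U[i, lo_c] += 1.0 - w
        U[i, hi_c] += w
    return U


class TrilinearUp3d:
    """Scale-2 trilinear upsampling, separable along the three axes."""

    def __init__(self, dtype=np.float32):
        self._dtype = dtype
        self._mats: dict[int, np.ndarray] = {}

    def params(self):
        return []

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _up_matrix(n, self._dtype)
        return self._mats[n]

    def _apply(self, x: np.ndarray, transpose: bool) -> np.ndarray:
        for axis in (1, 2, 3):
            n = x.shape[axis]
            U = self._mat(n // 2 if transpose else n)
            M = U.T if transpose else U
            x = np.moveaxis(
                (M @ np.moveaxis(x, axis, 0).reshape(n, -1)).reshape(
                    (M.shape[0],) + np.moveaxis(x, axis, 0).shape[1:]
                ),
                0, axis,
            )
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self._apply(x, transpose=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self._apply(dy, transpose=True)
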