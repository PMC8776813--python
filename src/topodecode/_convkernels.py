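"""JIT-compiled direct 3-D convolution kernels.

Stride-1 valid convolutions on ``(N, C, D1, D2, D3)`` arrays with the
innermost loop running along the contiguous time axis so it
vectorizes.  Written as explicit loops rather than im2col + GEMM: on a
single core the patch-matrix copies cost more than the arithmetic.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["conv3d_forward", "conv3d_grad_w", "conv3d_grad_x"]


@numba.njit(fastmath=True, cache=True)
def _fwd(x, w, b, out):  # pragma: no cover - exercised via wrapper
    N, C = x.shape[0], x.shape[1]
    F, k1, k2, k3 = w.shape[0], w.shape[2], w.shape[3], w.shape[4]
    O1, O2, O3 = out.shape[2], out.shape[3], out.shape[4]
    for n in range(N):
        for f in range(F):
            for r in range(O1):
                for c in range(O2):
                    acc = out[n, f, r, c]
                    acc[:] = b[f]
                    for cc in range(C):
                        for i in range(k1):
                            for j in range(k2):
                                xrow = x[n, cc, r + i, c + j]
                                for k in range(k3):
                                    wv = w[f, cc, i, j, k]
                                    for t in range(O3):
                                        acc[t] += wv * xrow[t + k]


@numba.njit(fastmath=True, cache=True)
def _grad_w(x, dout, dw):  # pragma: no cover
    N, C = x.shape[0], x.shape[1]
    F, k1, k2, k3 = dw.shape[0], dw.shape[2], dw.shape[3], dw.shape[4]
    O1, O2, O3 = dout.shape[2], dout.shape[3], dout.shape[4]
    for n in range(N):
        for f in range(F):
            for r in range(O1):
                for c in range(O2):
                    drow = dout[n, f, r, c]
                    for cc in range(C):
                        for i in range(k1):
                            for j in range(k2):
                                xrow = x[n, cc, r + i, c + j]
                                for k in range(k3):
                                    s = drow[0] - drow[0]  # dtype-matched zero
                                    for t in range(O3):
                                        s += drow[t] * xrow[t + k]
                                    dw[f, cc, i, j, k] += s


@numba.njit(fastmath=True, cache=True)
def _grad_x(dout, w, dx):  # pragma: no cover
    N, C = dx.shape[0], dx.shape[1]
    F, k1, k2, k3 = w.shape[0], w.shape[2], w.shape[3], w.shape[4]
    O1, O2, O3 = dout.shape[2], dout.shape[3], dout.shape[4]
    for n in range(N):
        for f in range(F):
            for r in range(O1):
                for c in range(O2):
                    drow = dout[n, f, r, c]
                    for cc in range(C):
                        for i in range(k1):
                            for j in range(k2):
                                xrow = dx[n, cc, r + i, c + j]
                                for k in range(k3):
                                    wv = w[f, cc, i, j, k]
                                    for t in range(O3):
                                        xrow[t + k] += wv * drow[t]


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid stride-1 convolution; x (N,C,D1,D2,D3), w (F,C,k1,k2,k3)."""
    o = tuple(x.shape[2 + i] - w.shape[2 + i] + 1 for i in range(3))
    out = np.empty((x.shape[0], w.shape[0], *o), dtype=x.dtype)
    _fwd(
        np.ascontiguousarray(x),
        np.ascontiguousarray(w),
        b.astype(x.dtype),
        out,
    )
    return out


def conv3d_grad_w(x: np.ndarray, dout: np.ndarray, kernel_shape) -> np.ndarray:
    dw = np.zeros(kernel_shape, dtype=x.dtype)
    _grad_w(np.ascontiguousarray(x), np.ascontiguousarray(dout), dw)
    return dw


def conv3d_grad_x(dout: np.ndarray, w: np.ndarray, x_shape) -> np.ndarray:
    dx = np.zeros(x_shape, dtype=dout.dtype)
    _grad_x(np.ascontiguousarray(dout), np.ascontiguousarray(w.astype(dout.dtype)), dx)
    return dx
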