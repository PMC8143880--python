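"""Low-level JIT kernels for the conv layers.

These are memory-bound inner loops (unfold/fold, depthwise conv, pooling,
interpolation) compiled with numba when available; plain-numpy fallbacks
keep the package importable without it. Padding is implicit (zero, width 1
for 3x3 kernels).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _im2col3_jit(x):
    N, C, H, W = x.shape
    cols = np.zeros((N, C * 9, H * W), dtype=x.dtype)
    for n in range(N):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    k = c * 9 + i * 3 + j
                    h0 = max(0, 1 - i)
                    h1 = min(H, H + 1 - i)
                    w0 = max(0, 1 - j)
                    w1 = min(W, W + 1 - j)
                    for h in range(h0, h1):
                        base = h * W
                        src_h = h + i - 1
                        cols[n, k, base + w0 : base + w1] = x[
                            n, c, src_h, w0 + j - 1 : w1 + j - 1
                        ]
    return cols


def _im2col3_np(x):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((N, C, 9, H, W), dtype=x.dtype)
    k = 0
    for i in range(3):
        for j in range(3):
            cols[:, :, k] = xp[:, :, i : i + H, j : j + W]
            k += 1
    return cols.reshape(N, C * 9, H * W)


@njit(cache=True, fastmath=True)
def _col2im3_jit(dcols, H, W):
    N = dcols.shape[0]
    C = dcols.shape[1] // 9
    dx = np.zeros((N, C, H, W), dtype=dcols.dtype)
    for n in range(N):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    k = c * 9 + i * 3 + j
                    h0 = max(0, 1 - i)
                    h1 = min(H, H + 1 - i)
                    w0 = max(0, 1 - j)
                    w1 = min(W, W + 1 - j)
                    for h in range(h0, h1):
                        base = h * W
                        dst_h = h + i - 1
                        dx[n, c, dst_h, w0 + j - 1 : w1 + j - 1] += dcols[
                            n, k, base + w0 : base + w1
                        ]
    return dx


def _col2im3_np(dcols, H, W):
    N = dcols.shape[0]
    C = dcols.shape[1] // 9
    d = dcols.reshape(N, C, 9, H, W)
    dxp = np.zeros((N, C, H + 2, W + 2), dtype=dcols.dtype)
    k = 0
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + H, j : j + W] += d[:, :, k]
            k += 1
    return dxp[:, :, 1 : 1 + H, 1 : 1 + W]


@njit(cache=True, fastmath=True)
def _depthwise_fwd_jit(x, w):
    N, C, H, W = x.shape
    y = np.zeros_like(x)
    for n in range(N):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    wij = w[c, i, j]
                    h0 = max(0, 1 - i)
                    h1 = min(H, H + 1 - i)
                    w0 = max(0, 1 - j)
                    w1 = min(W, W + 1 - j)
                    for h in range(h0, h1):
                        src_h = h + i - 1
                        for ww in range(w0, w1):
                            y[n, c, h, ww] += wij * x[n, c, src_h, ww + j - 1]
    return y


def _depthwise_fwd_np(x, w):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros_like(x)
    for i in range(3):
        for j in range(3):
            y += xp[:, :, i : i + H, j : j + W] * w[None, :, i, j, None, None]
    return y


@njit(cache=True, fastmath=True)
def _depthwise_bwd_jit(x, w, dy):
    N, C, H, W = x.shape
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for n in range(N):
        for c in range(C):
            for i in range(3):
                for j in range(3):
                    wij = w[c, i, j]
                    acc = np.float32(0.0)
                    h0 = max(0, 1 - i)
                    h1 = min(H, H + 1 - i)
                    w0 = max(0, 1 - j)
                    w1 = min(W, W + 1 - j)
                    for h in range(h0, h1):
                        src_h = h + i - 1
                        for ww in range(w0, w1):
                            g = dy[n, c, h, ww]
                            acc += g * x[n, c, src_h, ww + j - 1]
                            dx[n, c, src_h, ww + j - 1] += g * wij
                    dw[c, i, j] += acc
    return dx, dw


def _depthwise_bwd_np(x, w, dy):
    N, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    for i in range(3):
        for j in range(3):
            dw[:, i, j] = (dy * xp[:, :, i : i + H, j : j + W]).sum(axis=(0, 2, 3))
            dxp[:, :, i : i + H, j : j + W] += dy * w[None, :, i, j, None, None]
    return dxp[:, :, 1 : 1 + H, 1 : 1 + W], dw


# Dispatch: the unfold/fold ops are fastest as vectorized numpy slice copies;
# the depthwise conv (many small per-channel stencils) benefits from JIT loops.
im2col3 = _im2col3_np
col2im3 = _col2im3_np
if HAVE_NUMBA:
    depthwise_fwd = _depthwise_fwd_jit
    depthwise_bwd = _depthwise_bwd_jit
else:  # pragma: no cover
    depthwise_fwd = _depthwise_fwd_np
    depthwise_bwd = _depthwise_bwd_np
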