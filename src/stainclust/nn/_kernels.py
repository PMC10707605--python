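"""Hot inner loops of the convolution adjoints, JIT-compiled when numba
is importable and falling back to vectorized NumPy otherwise. Both paths
compute identical results; the NumPy path is the reference."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


def _im2col_np(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im_np(cols, xshape, kh, kw, stride, padding, ho, wo):
    n, c, h, w = xshape
    out = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=cols.dtype)
    v = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += v[
                :, :, :, :, i, j
            ]
    if padding:
        out = out[:, :, padding : padding + h, padding : padding + w]
    return out


if HAVE_NUMBA:

    @njit(cache=False)
    def _im2col_kernel(x, cols, kh, kw, stride, padding, ho, wo):  # pragma: no cover
        n, c, h, w = x.shape
        for ni in range(n):
            for oi in range(ho):
                for oj in range(wo):
                    row = (ni * ho + oi) * wo + oj
                    bi = oi * stride - padding
                    bj = oj * stride - padding
                    k = 0
                    for ci in range(c):
                        for i in range(kh):
                            src_i = bi + i
                            inside_i = 0 <= src_i < h
                            for j in range(kw):
                                src_j = bj + j
                                if inside_i and 0 <= src_j < w:
                                    cols[row, k] = x[ni, ci, src_i, src_j]
                                else:
                                    cols[row, k] = 0.0
                                k += 1

    @njit(cache=False)
    def _col2im_kernel(cols, out, kh, kw, stride, padding, ho, wo):  # pragma: no cover
        n, c, h, w = out.shape
        for ni in range(n):
            for oi in range(ho):
                for oj in range(wo):
                    row = (ni * ho + oi) * wo + oj
                    bi = oi * stride - padding
                    bj = oj * stride - padding
                    k = 0
                    for ci in range(c):
                        for i in range(kh):
                            src_i = bi + i
                            inside_i = 0 <= src_i < h
                            for j in range(kw):
                                src_j = bj + j
                                if inside_i and 0 <= src_j < w:
                                    out[ni, ci, src_i, src_j] += cols[row, k]
                                k += 1

    def im2col(x, kh, kw, stride, padding):
        n, c, h, w = x.shape
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (w + 2 * padding - kw) // stride + 1
        cols = np.empty((n * ho * wo, c * kh * kw), dtype=x.dtype)
        _im2col_kernel(np.ascontiguousarray(x), cols, kh, kw, stride, padding, ho, wo)
        return cols, ho, wo

    def col2im(cols, xshape, kh, kw, stride, padding, ho, wo):
        out = np.zeros(xshape, dtype=cols.dtype)
        _col2im_kernel(np.ascontiguousarray(cols), out, kh, kw, stride, padding, ho, wo)
        return out

else:  # pragma: no cover - exercised only without numba
    im2col = _im2col_np
    col2im = _col2im_np


# ------------------------------------------------- batched bilinear warp
def _warp_np(patches, rot, offset):
    n, c, h, w = patches.shape
    rr, cc = np.mgrid[0:h, 0:w]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    src = np.einsum("nij,pj->npi", rot, grid) + offset[:, None, :]
    r, col = src[..., 0], src[..., 1]
    r0 = np.floor(r).astype(np.int64)
    c0 = np.floor(col).astype(np.int64)
    dr = (r - r0)[:, None, :].astype(patches.dtype)
    dc = (col - c0)[:, None, :].astype(patches.dtype)

    def reflect(i, nn):
        if nn == 1:
            return np.zeros_like(i)
        i = np.mod(i, 2 * nn)
        return np.where(i >= nn, 2 * nn - 1 - i, i)

    flat = patches.reshape(n, c, h * w)

    def gather(ri, ci):
        idx = reflect(ri, h) * w + reflect(ci, w)
        return np.take_along_axis(flat, idx[:, None, :], axis=2)

    out = (
        gather(r0, c0) * (1 - dr) * (1 - dc)
        + gather(r0, c0 + 1) * (1 - dr) * dc
        + gather(r0 + 1, c0) * dr * (1 - dc)
        + gather(r0 + 1, c0 + 1) * dr * dc
    )
    return np.clip(out, 0.0, 1.0).reshape(n, c, h, w).astype(patches.dtype)


if HAVE_NUMBA:

    @njit(cache=False)
    def _warp_kernel(patches, rot, offset, out):  # pragma: no cover
        n, c, h, w = patches.shape
        for ni in range(n):
            a00 = rot[ni, 0, 0]
            a01 = rot[ni, 0, 1]
            a10 = rot[ni, 1, 0]
            a11 = rot[ni, 1, 1]
            o0 = offset[ni, 0]
            o1 = offset[ni, 1]
            for oi in range(h):
                for oj in range(w):
                    r = a00 * oi + a01 * oj + o0
                    cl = a10 * oi + a11 * oj + o1
                    r0 = int(np.floor(r))
                    c0 = int(np.floor(cl))
                    dr = r - r0
                    dc = cl - c0
                    ri0 = r0 % (2 * h)
                    if ri0 < 0:
                        ri0 += 2 * h
                    if ri0 >= h:
                        ri0 = 2 * h - 1 - ri0
                    ri1 = (r0 + 1) % (2 * h)
                    if ri1 < 0:
                        ri1 += 2 * h
                    if ri1 >= h:
                        ri1 = 2 * h - 1 - ri1
                    ci0 = c0 % (2 * w)
                    if ci0 < 0:
                        ci0 += 2 * w
                    if ci0 >= w:
                        ci0 = 2 * w - 1 - ci0
                    ci1 = (c0 + 1) % (2 * w)
                    if ci1 < 0:
                        ci1 += 2 * w
                    if ci1 >= w:
                        ci1 = 2 * w - 1 - ci1
                    w00 = (1.0 - dr) * (1.0 - dc)
                    w01 = (1.0 - dr) * dc
                    w10 = dr * (1.0 - dc)
                    w11 = dr * dc
                    for ci in range(c):
                        v = (
                            w00 * patches[ni, ci, ri0, ci0]
                            + w01 * patches[ni, ci, ri0, ci1]
                            + w10 * patches[ni, ci, ri1, ci0]
                            + w11 * patches[ni, ci, ri1, ci1]
                        )
                        if v < 0.0:
                            v = 0.0
                        elif v > 1.0:
                            v = 1.0
                        out[ni, ci, oi, oj] = v

    def warp_bilinear(patches, rot, offset):
        out = np.empty_like(patches)
        _warp_kernel(
            np.ascontiguousarray(patches),
            np.ascontiguousarray(rot, dtype=np.float64),
            np.ascontiguousarray(offset, dtype=np.float64),
            out,
        )
        return out

else:  # pragma: no cover
    warp_bilinear = _warp_np
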