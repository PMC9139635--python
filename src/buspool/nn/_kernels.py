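"""JIT-compiled inner loops for the hot layers (numba, with numpy fallback).

The depthwise convolution and the exact GELU dominate step time at the
tiny activation sizes this package trains at, where vectorized numpy is
per-call-overhead-bound.  The numba kernels remove that overhead; every
kernel has a numpy twin used when numba is unavailable, and the test
suite checks the two agree.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf as _scipy_erf

try:  # pragma: no cover - exercised implicitly by every model test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@njit(cache=True, fastmath=True)
def _dw_forward_nb(xp, wd, b, out):  # pragma: no cover - compiled
    n, H, W, c = out.shape
    k = wd.shape[0]
    for ni in range(n):
        for h in range(H):
            for w in range(W):
                for ci in range(c):
                    acc = b[ci]
                    for i in range(k):
                        for j in range(k):
                            acc += wd[i, j, ci] * xp[ni, h + i, w + j, ci]
                    out[ni, h, w, ci] = acc


@njit(cache=True, fastmath=True)
def _dw_grad_w_nb(xp, gout, gw):  # pragma: no cover - compiled
    n, H, W, c = gout.shape
    k = gw.shape[0]
    for ni in range(n):
        for h in range(H):
            for w in range(W):
                for ci in range(c):
                    g = gout[ni, h, w, ci]
                    for i in range(k):
                        for j in range(k):
                            gw[i, j, ci] += g * xp[ni, h + i, w + j, ci]


@njit(cache=True, fastmath=True)
def _dw_grad_x_nb(gp, wd, gx):  # pragma: no cover - compiled
    n, H, W, c = gx.shape
    k = wd.shape[0]
    for ni in range(n):
        for h in range(H):
            for w in range(W):
                for ci in range(c):
                    acc = 0.0
                    for i in range(k):
                        for j in range(k):
                            acc += wd[k - 1 - i, k - 1 - j, ci] * gp[ni, h + i, w + j, ci]
                    gx[ni, h, w, ci] = acc


@njit(cache=True, fastmath=True)
def _gelu_exact_nb(z, out):  # pragma: no cover - compiled
    flat_z = z.ravel()
    flat_o = out.ravel()
    for i in range(flat_z.size):
        v = flat_z[i]
        flat_o[i] = v * 0.5 * (1.0 + math.erf(v * _INV_SQRT2))


@njit(cache=True, fastmath=True)
def _gelu_exact_grad_nb(z, out):  # pragma: no cover - compiled
    flat_z = z.ravel()
    flat_o = out.ravel()
    for i in range(flat_z.size):
        v = flat_z[i]
        cdf = 0.5 * (1.0 + math.erf(v * _INV_SQRT2))
        flat_o[i] = cdf + v * math.exp(-0.5 * v * v) * _INV_SQRT_2PI


# -- public dispatchers ------------------------------------------------------

def dw_forward(xp: np.ndarray, wd: np.ndarray, b: np.ndarray, out: np.ndarray) -> None:
    """out[n,h,w,c] = b[c] + sum_ij wd[i,j,c] * xp[n,h+i,w+j,c]."""
    if HAVE_NUMBA:
        _dw_forward_nb(xp, wd, b, out)
        return
    k = wd.shape[0]
    h, w = out.shape[1], out.shape[2]
    out[...] = b
    for i in range(k):
        for j in range(k):
            out += wd[i, j] * xp[:, i : i + h, j : j + w, :]


def dw_grad_w(xp: np.ndarray, gout: np.ndarray, gw: np.ndarray) -> None:
    """Accumulate gw[i,j,c] += sum_nhw gout[n,h,w,c] * xp[n,h+i,w+j,c]."""
    if HAVE_NUMBA:
        _dw_grad_w_nb(xp, gout, gw)
        return
    k = gw.shape[0]
    h, w = gout.shape[1], gout.shape[2]
    for i in range(k):
        for j in range(k):
            gw[i, j] += (gout * xp[:, i : i + h, j : j + w, :]).sum(axis=(0, 1, 2))


def dw_grad_x(gp: np.ndarray, wd: np.ndarray, gx: np.ndarray) -> None:
    """gx = correlation of padded gout with the spatially flipped kernel."""
    if HAVE_NUMBA:
        _dw_grad_x_nb(gp, wd, gx)
        return
    k = wd.shape[0]
    h, w = gx.shape[1], gx.shape[2]
    gx[...] = 0.0
    for i in range(k):
        for j in range(k):
            gx += wd[k - 1 - i, k - 1 - j] * gp[:, i : i + h, j : j + w, :]


def gelu_exact(z: np.ndarray) -> np.ndarray:
    if HAVE_NUMBA:
        zc = np.ascontiguousarray(z)
        out = np.empty_like(zc)
        _gelu_exact_nb(zc, out)
        return out
    return z * 0.5 * (1.0 + _scipy_erf(z * _INV_SQRT2))


def gelu_exact_grad(z: np.ndarray) -> np.ndarray:
    if HAVE_NUMBA:
        zc = np.ascontiguousarray(z)
        out = np.empty_like(zc)
        _gelu_exact_grad_nb(zc, out)
        return out
    cdf = 0.5 * (1.0 + _scipy_erf(z * _INV_SQRT2))
    return cdf + z * np.exp(-0.5 * z * z) * _INV_SQRT_2PI
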