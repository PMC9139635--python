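"""Minimal CPU neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
exposes its learnable tensors as :class:`Param` objects.  There is no
autodiff graph — ``backward`` consumes the gradient w.r.t. the layer
output and returns the gradient w.r.t. the layer input, accumulating
parameter gradients in place.  All backward passes are verified against
central finite differences in the test suite.

Activations are stored channels-LAST, ``(batch, height, width, channels)``:
with channels contiguous, pointwise (1x1) convolutions and the classifier
head are single BLAS matmuls, LayerNorm reduces over a contiguous axis,
and the depthwise convolution becomes k*k shifted multiply-accumulates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from . import _kernels

SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))
GELU_TANH_CUBIC = 0.044715


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples re-drawn until within 2 std (truncated normal)."""
    out = rng.normal(0.0, std, size=shape)
    for _ in range(8):
        bad = np.abs(out) > 2.0 * std
        if not bad.any():
            break
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
    return np.clip(out, -2.0 * std, 2.0 * std)


class Layer:
    """Base class: stateless apart from params and the forward cache."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def gelu(z, mode: str = "exact"):
    """Gaussian error linear unit, z * Phi(z).

    ``exact`` evaluates z * 0.5 * (1 + erf(z / sqrt(2))); ``tanh`` uses the
    cubic tanh approximation 0.5*z*(1 + tanh(sqrt(2/pi)*(z + 0.044715 z^3))).
    """
    z = np.asarray(z, dtype=float)
    if mode == "exact":
        return z * 0.5 * (1.0 + erf(z / np.sqrt(2.0)))
    if mode == "tanh":
        inner = SQRT_2_OVER_PI * (z + GELU_TANH_CUBIC * z**3)
        return 0.5 * z * (1.0 + np.tanh(inner))
    raise ValueError(f"unknown gelu mode {mode!r}; expected 'exact' or 'tanh'")


def gelu_grad(z, mode: str = "exact"):
    z = np.asarray(z, dtype=float)
    if mode == "exact":
        phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
        cdf = 0.5 * (1.0 + erf(z / np.sqrt(2.0)))
        return cdf + z * phi
    if mode == "tanh":
        inner = SQRT_2_OVER_PI * (z + GELU_TANH_CUBIC * z**3)
        t = np.tanh(inner)
        dinner = SQRT_2_OVER_PI * (1.0 + 3.0 * GELU_TANH_CUBIC * z**2)
        return 0.5 * (1.0 + t) + 0.5 * z * (1.0 - t**2) * dinner
    raise ValueError(f"unknown gelu mode {mode!r}")


class GELU(Layer):
    def __init__(self, mode: str = "exact"):
        if mode not in ("exact", "tanh"):
            raise ValueError(f"unknown gelu mode {mode!r}")
        self.mode = mode
        self._z = None

    def forward(self, x):
        self._z = x
        if self.mode == "exact":
            return _kernels.gelu_exact(x)
        return gelu(x, self.mode)

    def backward(self, gout):
        if self.mode == "exact":
            return gout * _kernels.gelu_exact_grad(self._z)
        return gout * gelu_grad(self._z, self.mode)


def layer_norm(a: np.ndarray, epsilon: float = 1e-6, axis: int = -1) -> np.ndarray:
    """Normalize over *axis*: (a - mu) / (sigma + epsilon).

    ``mu`` and ``sigma`` are the per-sample mean and population standard
    deviation of the hidden units along *axis*; no minibatch statistics are
    involved, so a sample's output is independent of its batch context.
    """
    a = np.asarray(a, dtype=float)
    if a.shape[axis] < 1:
        raise ValueError("layer_norm needs at least one hidden unit")
    mu = a.mean(axis=axis, keepdims=True)
    sigma = np.sqrt(((a - mu) ** 2).mean(axis=axis, keepdims=True))
    return (a - mu) / (sigma + epsilon)


class LayerNorm(Layer):
    """LayerNorm over the trailing (channel) axis with learnable scale/shift.

    For 4-D input (N, H, W, C) every spatial position is normalized over
    its C channels independently.  Scale initializes to 1 and shift to 0.
    """

    def __init__(self, num_channels: int, epsilon: float = 1e-6, name: str = "ln"):
        self.eps = float(epsilon)
        self.gamma = Param(f"{name}.gamma", np.ones(num_channels))
        self.beta = Param(f"{name}.beta", np.zeros(num_channels))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        sigma = np.sqrt(((x - mu) ** 2).mean(axis=-1, keepdims=True))
        denom = sigma + self.eps
        xhat = (x - mu) / denom
        self._cache = (xhat, sigma, denom)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, gout):
        xhat, sigma, denom = self._cache
        flat_axes = tuple(range(gout.ndim - 1))
        self.gamma.grad += (gout * xhat).sum(axis=flat_axes)
        self.beta.grad += gout.sum(axis=flat_axes)
        u = gout * self.gamma.data  # dL/dxhat
        mean_u = u.mean(axis=-1, keepdims=True)
        mean_ux = (u * xhat).mean(axis=-1, keepdims=True)
        # xhat = (x - mu)/(sigma + eps); the sigma path carries a 1/sigma factor
        sigma_safe = np.maximum(sigma, 1e-30)
        return (u - mean_u) / denom - xhat * mean_ux / sigma_safe


class PatchConv(Layer):
    """Non-overlapping k x k convolution with stride k (patchify / downsample).

    Equivalent to reshaping the image into k x k patches and applying one
    linear map; weights are stored as (k, k, C_in, C_out).
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator, name: str = "patch"):
        self.k = k
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.w = Param(f"{name}.w", trunc_normal(rng, (k, k, in_ch, out_ch)))
        self.b = Param(f"{name}.b", np.zeros(out_ch))
        self._v = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        n, h, w, c = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"spatial size {h}x{w} not divisible by patch size {k}")
        ho, wo = h // k, w // k
        v = (
            x.reshape(n, ho, k, wo, k, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, ho, wo, k * k * c)
        )
        self._v, self._xshape = v, x.shape
        out = v @ self.w.data.reshape(k * k * c, self.out_ch)
        return out + self.b.data

    def backward(self, gout):
        n, h, w, c = self._xshape
        k = self.k
        ho, wo = h // k, w // k
        kkc = k * k * c
        gflat = gout.reshape(-1, self.out_ch)
        self.w.grad += (self._v.reshape(-1, kkc).T @ gflat).reshape(self.w.data.shape)
        self.b.grad += gflat.sum(axis=0)
        gv = gflat @ self.w.data.reshape(kkc, self.out_ch).T
        return (
            gv.reshape(n, ho, wo, k, k, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h, w, c)
        )


class DepthwiseConv(Layer):
    """k x k depthwise convolution (groups == channels), stride 1, same padding.

    Implemented as k*k shifted multiply-accumulates over the zero-padded
    input; weights are stored as (k, k, C).
    """

    def __init__(self, channels: int, k: int, rng: np.random.Generator, name: str = "dw"):
        if k % 2 == 0:
            raise ValueError("depthwise kernel size must be odd")
        self.k = k
        self.pad = k // 2
        self.w = Param(f"{name}.w", trunc_normal(rng, (k, k, channels)))
        self.b = Param(f"{name}.b", np.zeros(channels))
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        pad = self.pad
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        out = np.empty_like(x)
        _kernels.dw_forward(xp, self.w.data, self.b.data, out)
        return out

    def backward(self, gout):
        pad = self.pad
        gout = np.ascontiguousarray(gout)
        _kernels.dw_grad_w(self._xp, gout, self.w.grad)
        self.b.grad += gout.sum(axis=(0, 1, 2))
        # input gradient = correlation of gout with the spatially flipped kernel
        gp = np.pad(gout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        gx = np.empty_like(gout)
        _kernels.dw_grad_x(gp, self.w.data, gx)
        return gx


class PointwiseConv(Layer):
    """1 x 1 convolution: per-position linear map across channels."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str = "pw"):
        self.w = Param(f"{name}.w", trunc_normal(rng, (in_ch, out_ch)))
        self.b = Param(f"{name}.b", np.zeros(out_ch))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, gout):
        in_ch, out_ch = self.w.data.shape
        self.w.grad += self._x.reshape(-1, in_ch).T @ gout.reshape(-1, out_ch)
        self.b.grad += gout.reshape(-1, out_ch).sum(axis=0)
        return gout @ self.w.data.T


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str = "fc"):
        self.w = Param(f"{name}.w", trunc_normal(rng, (in_dim, out_dim)))
        self.b = Param(f"{name}.b", np.zeros(out_dim))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.w.data + self.b.data

    def backward(self, gout):
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.data.T


class GlobalAvgPool(Layer):
    """(N, H, W, C) -> (N, C) spatial mean."""

    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, gout):
        n, h, w, c = self._shape
        return np.broadcast_to(gout.reshape(n, 1, 1, c), self._shape) / (h * w)


class ConvNeXtBlock(Layer):
    """Depthwise 7x7 -> LayerNorm -> 1x1 expand -> GELU -> 1x1 project, + residual.

    Spatial size and channel count are preserved; with all convolution
    weights and affine shifts at zero the block is the identity map.
    """

    def __init__(
        self,
        channels: int,
        rng: np.random.Generator,
        dw_kernel: int = 7,
        expansion_ratio: int = 4,
        epsilon: float = 1e-6,
        gelu_mode: str = "exact",
        name: str = "block",
    ):
        hidden = channels * expansion_ratio
        self.inner = [
            DepthwiseConv(channels, dw_kernel, rng, name=f"{name}.dw"),
            LayerNorm(channels, epsilon, name=f"{name}.ln"),
            PointwiseConv(channels, hidden, rng, name=f"{name}.pw1"),
            GELU(gelu_mode),
            PointwiseConv(hidden, channels, rng, name=f"{name}.pw2"),
        ]

    def params(self):
        return [p for layer in self.inner for p in layer.params()]

    def forward(self, x):
        h = x
        for layer in self.inner:
            h = layer.forward(h)
        return x + h

    def backward(self, gout):
        g = gout
        for layer in reversed(self.inner):
            g = layer.backward(g)
        return gout + g
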