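"""Layer-level numerics: GELU, LayerNorm, convolutions, gradients, Adam.

Every backward pass is validated against central finite differences — the
only trustworthy oracle for hand-written backprop.
"""

import numpy as np
import pytest
from scipy.stats import norm

from buspool.nn import _kernels
from buspool.nn.layers import (
    ConvNeXtBlock,
    DepthwiseConv,
    GELU,
    GlobalAvgPool,
    LayerNorm,
    Linear,
    PatchConv,
    PointwiseConv,
    gelu,
    gelu_grad,
    layer_norm,
)
from buspool.nn.optim import Adam


class TestGelu:
    def test_zero_maps_to_zero(self):
        assert gelu(0.0, "exact") == 0.0
        assert gelu(0.0, "tanh") == 0.0

    def test_gelu_one_matches_normal_cdf(self):
        # z * Phi(z) at z=1, against scipy's high-precision normal CDF
        assert gelu(1.0, "exact") == pytest.approx(1.0 * norm.cdf(1.0), abs=1e-5)

    def test_exact_vs_tanh_approximation_close_on_grid(self):
        z = np.linspace(-5, 5, 10_000)
        assert np.abs(gelu(z, "exact") - gelu(z, "tanh")).max() < 1e-2

    def test_reflection_identity(self):
        # Phi(z) + Phi(-z) = 1 implies gelu(z) - gelu(-z) = z
        z = np.linspace(-6, 6, 1001)
        assert np.abs((gelu(z, "exact") - gelu(-z, "exact")) - z).max() < 1e-12

    def test_gradient_matches_finite_differences(self):
        z = np.linspace(-4, 4, 81)
        eps = 1e-6
        for mode in ("exact", "tanh"):
            numeric = (gelu(z + eps, mode) - gelu(z - eps, mode)) / (2 * eps)
            assert np.abs(gelu_grad(z, mode) - numeric).max() < 1e-8

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            gelu(1.0, "relu")

    def test_jit_kernel_agrees_with_reference(self, rng):
        z = rng.normal(size=(4, 5, 6)) * 3
        assert np.abs(_kernels.gelu_exact(z) - gelu(z, "exact")).max() < 1e-12
        assert np.abs(_kernels.gelu_exact_grad(z) - gelu_grad(z, "exact")).max() < 1e-12


class TestLayerNormFunction:
    def test_two_point_example(self):
        out = layer_norm(np.array([1.0, 3.0]))
        assert out == pytest.approx([-1.0, 1.0], abs=1e-5)

    def test_constant_vector_maps_to_zeros(self):
        assert np.allclose(layer_norm(np.full(8, 3.3)), 0.0)

    def test_normalization_contract_random_vectors(self, rng):
        for _ in range(20):
            v = rng.normal(size=64) * rng.uniform(0.5, 20)
            out = layer_norm(v)
            assert abs(out.mean()) < 1e-6
            assert np.var(out) == pytest.approx(1.0, abs=1e-4)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            layer_norm(np.empty(0))

    def test_batch_size_independence(self, rng):
        """Pure per-sample statistics: a sample's output never depends on
        which minibatch it sits in."""
        layer = LayerNorm(12)
        single = rng.normal(size=(1, 12))
        batch = np.concatenate([single, rng.normal(size=(7, 12))])
        assert np.allclose(layer.forward(single)[0], layer.forward(batch)[0])


def _gradcheck(layer, x, eps=1e-6, tol=1e-7):
    """Central finite differences for input and parameter gradients."""
    out = layer.forward(x)
    gout = np.random.default_rng(99).random(out.shape)

    def loss():
        return float((layer.forward(x) * gout).sum())

    for p in layer.params():
        p.zero_grad()
    layer.forward(x)
    gx = layer.backward(gout)

    num = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        up = loss()
        x[i] = orig - eps
        down = loss()
        x[i] = orig
        num[i] = (up - down) / (2 * eps)
    assert np.abs(gx - num).max() < tol, "input gradient mismatch"

    layer.forward(x)
    for p in layer.params():
        flat, g = p.data.ravel(), p.grad.ravel()
        for k in range(min(flat.size, 12)):
            orig = flat[k]
            flat[k] = orig + eps
            up = loss()
            flat[k] = orig - eps
            down = loss()
            flat[k] = orig
            assert abs(g[k] - (up - down) / (2 * eps)) < tol, f"param gradient mismatch: {p.name}"


@pytest.mark.parametrize(
    "build,shape",
    [
        (lambda rng: DepthwiseConv(3, 3, rng), (2, 6, 6, 3)),
        (lambda rng: DepthwiseConv(2, 7, rng), (1, 8, 8, 2)),
        (lambda rng: PatchConv(3, 4, 2, rng), (2, 6, 6, 3)),
        (lambda rng: PatchConv(1, 5, 4, rng), (1, 8, 8, 1)),
        (lambda rng: PointwiseConv(3, 5, rng), (2, 4, 4, 3)),
        (lambda rng: LayerNorm(3), (2, 4, 4, 3)),
        (lambda rng: GELU("exact"), (2, 4, 4, 3)),
        (lambda rng: GELU("tanh"), (2, 4, 4, 3)),
        (lambda rng: GlobalAvgPool(), (2, 4, 4, 3)),
        (lambda rng: Linear(6, 2, rng), (5, 6)),
        (lambda rng: ConvNeXtBlock(3, rng, dw_kernel=3, expansion_ratio=2), (2, 5, 5, 3)),
    ],
    ids=["dw3", "dw7", "patch2", "patch4", "pointwise", "layernorm",
         "gelu-exact", "gelu-tanh", "gap", "linear", "block"],
)
def test_backward_matches_finite_differences(build, shape, rng):
    layer = build(rng)
    x = rng.random(shape) - 0.3
    _gradcheck(layer, x)


class TestConvNeXtBlock:
    def test_zero_weights_make_identity(self, rng):
        block = ConvNeXtBlock(4, rng)
        for p in block.params():
            if not p.name.endswith(".gamma"):  # scale stays at its identity init
                p.data[...] = 0.0
        x = rng.random((2, 6, 6, 4))
        assert np.allclose(block.forward(x), x)

    def test_shape_preservation(self, rng):
        block = ConvNeXtBlock(16, rng)
        x = rng.random((1, 28, 28, 16))
        assert block.forward(x).shape == x.shape

    def test_hand_computed_single_pixel_forward(self, rng):
        """1x1 spatial, single channel: the whole block reduces to a chain
        of scalars that can be followed by hand.  LayerNorm of a single
        channel is identically its shift (beta = 0 at init), so the
        transform branch is gelu(pw1 bias) scaled by the pw2 weight."""
        block = ConvNeXtBlock(1, rng, dw_kernel=3, expansion_ratio=1)
        x = np.array([[[[0.7]]]])
        pw1_b = next(p for p in block.params() if p.name.endswith("pw1.b"))
        pw2_w = next(p for p in block.params() if p.name.endswith("pw2.w"))
        pw2_b = next(p for p in block.params() if p.name.endswith("pw2.b"))
        expected = 0.7 + float(gelu(pw1_b.data[0], "exact")) * pw2_w.data[0, 0] + pw2_b.data[0]
        assert block.forward(x)[0, 0, 0, 0] == pytest.approx(expected, abs=1e-12)


class TestDepthwiseKernels:
    def test_jit_and_numpy_paths_agree(self, rng):
        xp = rng.random((2, 10, 10, 5))
        wd = rng.random((3, 3, 5))
        b = rng.random(5)
        gout = rng.random((2, 8, 8, 5))
        out_jit = np.empty((2, 8, 8, 5))
        gw_jit = np.zeros((3, 3, 5))
        gx_jit = np.empty((2, 8, 8, 5))
        _kernels.dw_forward(xp, wd, b, out_jit)
        _kernels.dw_grad_w(xp, gout, gw_jit)
        _kernels.dw_grad_x(np.pad(gout, ((0, 0), (1, 1), (1, 1), (0, 0))), wd, gx_jit)

        was = _kernels.HAVE_NUMBA
        _kernels.HAVE_NUMBA = False
        try:
            out_np = np.empty((2, 8, 8, 5))
            gw_np = np.zeros((3, 3, 5))
            gx_np = np.empty((2, 8, 8, 5))
            _kernels.dw_forward(xp, wd, b, out_np)
            _kernels.dw_grad_w(xp, gout, gw_np)
            _kernels.dw_grad_x(np.pad(gout, ((0, 0), (1, 1), (1, 1), (0, 0))), wd, gx_np)
        finally:
            _kernels.HAVE_NUMBA = was
        assert np.abs(out_jit - out_np).max() < 1e-12
        assert np.abs(gw_jit - gw_np).max() < 1e-12
        assert np.abs(gx_jit - gx_np).max() < 1e-12


class TestAdam:
    def test_single_step_matches_closed_form(self):
        from buspool.nn.layers import Param

        p = Param("w", np.array([1.0, -2.0]))
        p.grad[...] = np.array([0.5, -1.0])
        opt = Adam([p], lr=0.1, beta1=0.5, beta2=0.99)
        opt.step()
        # bias-corrected first step: m_hat = g, v_hat = g^2 -> step = lr*sign(g)
        expected = np.array([1.0, -2.0]) - 0.1 * np.sign([0.5, -1.0]) / (1 + 1e-8 / np.abs([0.5, -1.0]))
        assert p.data == pytest.approx(expected, abs=1e-6)

    def test_invalid_betas_rejected(self):
        with pytest.raises(ValueError):
            Adam([], beta1=0.0)
        with pytest.raises(ValueError):
            Adam([], beta2=1.0)

    def test_converges_on_quadratic(self):
        from buspool.nn.layers import Param

        p = Param("w", np.array([5.0]))
        opt = Adam([p], lr=0.1, beta1=0.5, beta2=0.99)
        for _ in range(500):
            opt.zero_grad()
            p.grad[...] = 2 * p.data  # d/dw of w^2
            opt.step()
        assert abs(p.data[0]) < 1e-2
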