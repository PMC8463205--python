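"""Forward convolution and hand-derived backpropagation.

The central correctness property is the finite-difference gradient
check: analytic gradients of all weights and biases must match central
differences for every supported loss.
"""

import numpy as np
import pytest

from srmri import losses
from srmri.exceptions import ConfigurationError, ShapeError
from srmri.network import (
    ConvLayer,
    GradientSet,
    SRCNNModel,
    backward,
    conv_forward,
    forward,
    relu,
)


def brute_force_conv(x, weights, bias):
    """Nested-loop cross-correlation with zero 'same' padding."""
    o_ch, c_ch, kh, kw = weights.shape
    c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    out = np.zeros((o_ch, h, w))
    for o in range(o_ch):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for c_i in range(c_ch):
                    for u in range(kh):
                        for v in range(kw):
                            ii, jj = i + u - ph, j + v - pw
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += x[c_i, ii, jj] * weights[o, c_i, u, v]
                out[o, i, j] = acc + bias[o]
    return out


def small_model(seed=1, final_bias=0.5):
    """3-layer model whose outputs land inside (0, 1), so the two
    logarithmic losses are differentiable away from the clamp."""
    model = SRCNNModel.build(kernel_sizes=(3, 3, 3), channels=(4, 3), seed=seed, scale=0.3)
    model.layers[-1].bias[:] = final_bias
    return model


class TestRelu:
    @pytest.mark.parametrize("x,expected", [(2.5, 2.5), (-3.0, 0.0), (0.0, 0.0)])
    def test_scalar_branches(self, x, expected):
        assert relu(x) == expected


class TestConvForward:
    def test_identity_kernel(self, rng):
        x = rng.random((6, 6))
        layer = ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1), apply_relu=False)
        np.testing.assert_array_equal(conv_forward(x, layer)[0], x)

    def test_zero_weights_constant_bias(self, rng):
        x = rng.random((2, 5, 5))
        layer = ConvLayer(np.zeros((3, 2, 3, 3)), np.array([1.0, -2.0, 0.5]), apply_relu=False)
        out = conv_forward(x, layer)
        for o, b in enumerate([1.0, -2.0, 0.5]):
            np.testing.assert_allclose(out[o], b)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(size=(1, 4, 4))
        w = rng.normal(size=(1, 1, 3, 3))
        b = rng.normal(size=1)
        layer = ConvLayer(w, b, apply_relu=False)
        np.testing.assert_allclose(conv_forward(x, layer), brute_force_conv(x, w, b), atol=1e-12)

    def test_multichannel_matches_brute_force(self, rng):
        x = rng.normal(size=(3, 5, 5))
        w = rng.normal(size=(2, 3, 3, 3))
        b = rng.normal(size=2)
        layer = ConvLayer(w, b, apply_relu=True)
        expected = np.maximum(brute_force_conv(x, w, b), 0.0)
        np.testing.assert_allclose(conv_forward(x, layer), expected, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        layer = ConvLayer(np.zeros((1, 2, 3, 3)), np.zeros(1), apply_relu=False)
        with pytest.raises(ShapeError):
            conv_forward(rng.random((3, 4, 4)), layer)

    def test_even_kernel_rejected(self):
        with pytest.raises(ShapeError):
            ConvLayer(np.zeros((1, 1, 2, 2)), np.zeros(1))

    def test_bias_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            ConvLayer(np.zeros((2, 1, 3, 3)), np.zeros(3))


class TestForward:
    def test_identity_network(self, rng):
        x = rng.random((8, 8))
        model = SRCNNModel(
            [ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1), apply_relu=False)]
        )
        np.testing.assert_array_equal(forward(model, x), x)

    def test_zero_final_layer_gives_zero_output(self, rng):
        model = small_model()
        model.layers[-1].weights[:] = 0.0
        model.layers[-1].bias[:] = 0.0
        np.testing.assert_array_equal(forward(model, rng.random((8, 8))), 0.0)

    def test_three_layer_matches_composed_oracles(self, rng):
        model = small_model(seed=4)
        x = rng.random((16, 16))
        stack = x[None]
        for layer in model.layers:
            stack = brute_force_conv(stack, layer.weights, layer.bias)
            if layer.apply_relu:
                stack = np.maximum(stack, 0.0)
        np.testing.assert_allclose(forward(model, x), stack[0], atol=1e-10)

    def test_deterministic(self, rng):
        model = small_model()
        x = rng.random((8, 8))
        np.testing.assert_array_equal(forward(model, x), forward(model, x))

    def test_translation_equivariance_interior(self, rng):
        """Shifting the input shifts the output identically away from the
        padded border (bias-free single conv layer)."""
        x = rng.random((16, 16))
        layer = ConvLayer(rng.normal(size=(1, 1, 3, 3)), np.zeros(1), apply_relu=False)
        model = SRCNNModel([layer])
        y = forward(model, x)
        y_shift = forward(model, np.roll(x, 2, axis=1))
        np.testing.assert_allclose(
            y_shift[4:-4, 4:-4], np.roll(y, 2, axis=1)[4:-4, 4:-4], atol=1e-12
        )

    def test_final_relu_rejected(self):
        with pytest.raises(ConfigurationError):
            SRCNNModel([ConvLayer(np.ones((1, 1, 1, 1)), np.zeros(1), apply_relu=True)])

    def test_channel_chain_mismatch_rejected(self):
        l1 = ConvLayer(np.zeros((4, 1, 3, 3)), np.zeros(4))
        l2 = ConvLayer(np.zeros((1, 3, 3, 3)), np.zeros(1), apply_relu=False)
        with pytest.raises(ShapeError):
            SRCNNModel([l1, l2])


def finite_difference_grads(model, x, t, kind, h=1e-5):
    fd = []
    for p in model.parameters():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + h
            lp = losses.loss_value(forward(model, x), t, kind)
            p[idx] = orig - h
            lm = losses.loss_value(forward(model, x), t, kind)
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        fd.append(g)
    return fd


class TestBackward:
    @pytest.mark.parametrize("kind", losses.LOSS_KINDS)
    def test_gradients_match_finite_differences(self, rng, kind):
        """Analytic backpropagation vs central differences, rel err < 1e-4,
        on a random 3-layer model with an 8x8 input."""
        model = small_model(seed=2)
        x = rng.uniform(0.2, 0.8, (8, 8))
        t = rng.uniform(0.2, 0.8, (8, 8))
        analytic = backward(model, x, t, kind).flat()
        fd = finite_difference_grads(model, x, t, kind)
        for a, f in zip(analytic, fd):
            denom = np.maximum(np.maximum(np.abs(a), np.abs(f)), 1e-8)
            assert np.max(np.abs(a - f) / denom) < 1e-4

    def test_zero_gradient_at_loss_minimum(self, rng):
        """If the target equals the forward output, every MSE gradient is 0."""
        model = small_model(seed=3)
        x = rng.uniform(0.2, 0.8, (8, 8))
        t = forward(model, x)
        for g in backward(model, x, t, "mse").flat():
            np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_mse_gradients_linear_in_residual(self, rng):
        """Doubling the residual (hence 4x the loss) doubles every MSE
        gradient entry — differentiation is linear."""
        model = small_model(seed=5)
        x = rng.uniform(0.2, 0.8, (8, 8))
        pred = forward(model, x)
        r = rng.normal(0, 0.05, (8, 8))
        g1 = backward(model, x, pred - r, "mse").flat()
        g2 = backward(model, x, pred - 2 * r, "mse").flat()
        for a, b in zip(g1, g2):
            np.testing.assert_allclose(b, 2 * a, atol=1e-12)

    def test_unsupported_loss_rejected(self, rng):
        model = small_model()
        with pytest.raises(ConfigurationError):
            backward(model, rng.random((8, 8)), rng.random((8, 8)), "perceptual")

    def test_gradient_shapes_mirror_model(self, rng):
        model = small_model()
        grads = backward(model, rng.random((8, 8)), rng.random((8, 8)), "mse")
        assert isinstance(grads, GradientSet)
        for layer, dw, db in zip(model.layers, grads.weight_grads, grads.bias_grads):
            assert dw.shape == layer.weights.shape
            assert db.shape == layer.bias.shape


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, rng):
        model = small_model(seed=9)
        path = tmp_path / "model.npz"
        model.save(path, metadata={"note": "roundtrip"})
        loaded = SRCNNModel.load(path)
        x = rng.random((8, 8))
        np.testing.assert_array_equal(forward(loaded, x), forward(model, x))
        for a, b in zip(model.layers, loaded.layers):
            assert a.apply_relu == b.apply_relu
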