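"""Architecture contracts and backpropagation correctness."""

import numpy as np
import pytest

from burntseg.nn import (Adam, ModelSpec, build_custom_unet, build_unet_gru,
                         categorical_crossentropy, compile_model,
                         crossentropy_grad_logits)
from burntseg.nn.layers import GRU, Conv2D, ConvTranspose2x2, MaxPool2x2


def small_spec(arch, **kw):
    defaults = dict(architecture=arch, input_hw=(16, 16), in_channels=3,
                    base_filters=2, depth=2, dropout=0.2, seed=0)
    defaults.update(kw)
    return ModelSpec(**defaults)


class TestSpecValidation:
    def test_default_scales_match_published_architectures(self):
        cu = ModelSpec(architecture="custom_unet")
        assert cu.base_filters == 16
        assert cu.encoder_filters == [16, 32, 64, 128]
        assert cu.bottleneck_filters == 256
        ug = ModelSpec(architecture="unet_gru")
        assert ug.base_filters == 64
        assert ug.encoder_filters == [64, 128, 256, 512]
        assert ug.bottleneck_filters == 1024
        assert ug.resolved_gru_units() == 512
        assert ug.decoder_filters == [512, 256, 128, 64]

    def test_input_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="custom_unet", input_hw=(100, 100), depth=4)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(architecture="resnet")


class TestForwardContracts:
    def test_custom_unet_output_is_probability_map(self):
        model = build_custom_unet(small_spec("custom_unet"))
        x = np.random.default_rng(0).random((2, 16, 16, 3))
        probs = model.forward(x)
        assert probs.shape == (2, 16, 16, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_unet_gru_output_is_probability_map(self):
        model = build_unet_gru(small_spec("unet_gru"))
        x = np.random.default_rng(0).random((2, 16, 16, 3))
        probs = model.forward(x)
        assert probs.shape == (2, 16, 16, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_bottleneck_spatial_size_is_input_over_2_pow_depth(self):
        model = build_custom_unet(small_spec("custom_unet", input_hw=(64, 32),
                                             depth=3))
        assert model.bottleneck_hw == (8, 4)

    def test_gru_sequence_geometry(self):
        model = build_unet_gru(small_spec("unet_gru", input_hw=(32, 32), depth=2,
                                          base_filters=4))
        assert model.bottleneck_hw == (8, 8)
        assert model.sequence_length == 64
        assert model.gru.d_in == model.spec.bottleneck_filters
        assert model.gru.units == model.spec.resolved_gru_units()

    def test_batch_order_permutation_invariance(self):
        """No state leaks across samples: permuting the batch permutes outputs."""
        model = build_unet_gru(small_spec("unet_gru"))
        x = np.random.default_rng(3).random((3, 16, 16, 3))
        out = model.forward(x)
        out_perm = model.forward(x[[2, 0, 1]])
        np.testing.assert_allclose(out_perm, out[[2, 0, 1]], atol=1e-6)

    def test_minimal_depth_layer_inventory(self):
        model = build_custom_unet(ModelSpec(architecture="custom_unet",
                                            input_hw=(8, 8), in_channels=1,
                                            base_filters=1, depth=1, seed=0))
        inv = model.layer_inventory()
        assert inv["MaxPool2x2"] == 1
        assert inv["ConvTranspose2x2"] == 1
        assert inv["skip_concat"] == 1

    def test_gru_identity_scale_bypass_keeps_shapes(self):
        """With gru_units equal to the bottleneck width the decoder still
        mirrors a plain (deeper) UNet shape-wise."""
        spec = small_spec("unet_gru", gru_units=None)
        spec.gru_units = spec.bottleneck_filters
        model = build_unet_gru(spec)
        x = np.random.default_rng(1).random((1, 16, 16, 3))
        assert model.forward(x).shape == (1, 16, 16, 2)

    def test_same_seed_same_weights(self):
        m1 = build_custom_unet(small_spec("custom_unet", seed=5))
        m2 = build_custom_unet(small_spec("custom_unet", seed=5))
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a.value, b.value)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.zeros((1, 2, 2, 2))
        y[..., 1] = 1
        assert categorical_crossentropy(y, y) < 1e-9

    def test_uniform_prediction_is_ln2(self):
        y = np.zeros((1, 2, 2, 2))
        y[..., 0] = 1
        p = np.full_like(y, 0.5)
        assert categorical_crossentropy(p, y) == pytest.approx(np.log(2))

    def test_two_pixel_closed_form(self):
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert categorical_crossentropy(p, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.1643, abs=5e-5)

    def test_compile_rejects_nonpositive_lr(self):
        model = build_custom_unet(small_spec("custom_unet"))
        with pytest.raises(ValueError):
            compile_model(model, lr=0.0)


def numerical_gradient_check(model, x, y, n_probes=3, eps=1e-6):
    probs = model.forward(x, train=True)
    model.zero_grad()
    model.backward(crossentropy_grad_logits(probs, y))
    worst = 0.0
    rng = np.random.default_rng(0)
    for p in model.params():
        flat = p.value.ravel()
        for i in rng.integers(0, flat.size, size=min(n_probes, flat.size)):
            old = flat[i]
            flat[i] = old + eps
            lp = categorical_crossentropy(model.forward(x), y)
            flat[i] = old - eps
            lm = categorical_crossentropy(model.forward(x), y)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = p.grad.ravel()[i]
            worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
    return worst


class TestBackpropagation:
    @pytest.mark.parametrize("arch,builder", [
        ("custom_unet", build_custom_unet), ("unet_gru", build_unet_gru)])
    def test_analytic_gradients_match_numerical(self, arch, builder):
        spec = ModelSpec(architecture=arch, input_hw=(8, 8), in_channels=2,
                         base_filters=2, depth=2, dropout=0.0, seed=1,
                         dtype="float64")
        model = builder(spec)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 2))
        sel = rng.random((2, 8, 8)) > 0.5
        y = np.stack([~sel, sel], axis=-1).astype(float)
        assert numerical_gradient_check(model, x, y) < 1e-4

    def test_gru_layer_exact_gradients(self):
        rng = np.random.default_rng(3)
        gru = GRU(3, 4, rng, np.float64)
        x = rng.random((2, 5, 3))
        out = gru.forward(x, train=True)
        dout = rng.random(out.shape)
        for p in gru.params():
            p.grad[...] = 0
        dx = gru.backward(dout)
        def f():
            return float(np.sum(gru.forward(x) * dout))
        xf = x.ravel()
        for i in range(0, xf.size, 7):
            old = xf[i]
            xf[i] = old + 1e-6
            lp = f()
            xf[i] = old - 1e-6
            lm = f()
            xf[i] = old
            assert (lp - lm) / 2e-6 == pytest.approx(dx.ravel()[i], rel=1e-5)

    def test_adam_descends_on_quadratic(self):
        from burntseg.nn.layers import Param
        p = Param(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            p.grad[...] = 2 * p.value  # d/dx of x^2
            opt.step()
        assert np.abs(p.value).max() < 0.1

    def test_training_step_reduces_loss_on_separable_batch(self):
        model = build_custom_unet(small_spec("custom_unet", dropout=0.0))
        trainable = compile_model(model, lr=1e-3)
        rng = np.random.default_rng(0)
        cls = (rng.random((4, 16, 16)) > 0.5)
        x = np.where(cls[..., None], 0.8, 0.2) + rng.normal(0, 0.02, (4, 16, 16, 3))
        y = np.stack([~cls, cls], axis=-1).astype(float)
        first, _ = trainable.train_step(x, y)
        for _ in range(30):
            last, _ = trainable.train_step(x, y)
        assert last < first


class TestLayerPrimitives:
    def test_maxpool_backward_routes_to_argmax(self):
        x = np.array([[[[1.0], [2.0]], [[3.0], [4.0]]]])  # 1x2x2x1
        pool = MaxPool2x2()
        out = pool.forward(x, train=True)
        assert out[0, 0, 0, 0] == 4.0
        dx = pool.backward(np.ones_like(out))
        assert dx[0, 1, 1, 0] == 1.0 and dx.sum() == 1.0

    def test_transposed_conv_doubles_spatial_size(self):
        up = ConvTranspose2x2(3, 2, np.random.default_rng(0))
        out = up.forward(np.random.default_rng(1).random((1, 5, 7, 3)).astype(np.float32))
        assert out.shape == (1, 10, 14, 2)

    def test_conv_same_padding_preserves_shape(self):
        conv = Conv2D(2, 4, 3, np.random.default_rng(0))
        out = conv.forward(np.zeros((1, 9, 11, 2), np.float32))
        assert out.shape == (1, 9, 11, 4)
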