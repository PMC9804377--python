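"""Architecture geometry, initialization, gradients, persistence."""

import numpy as np
import pytest

from corrseg.nn import (
    CONTEXT, NetworkConfig, SGDNesterov, UNet, build_network, masked_loss,
    softmax_fg,
)
from corrseg.nn.layers import Conv2d, GroupNorm, MaxPool2, NearestResize


def _cast64(layer):
    for p in layer.params():
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    return layer


def _numeric_vs_analytic(layer, x, rng, fwd=None, n_probe=6, eps=1e-6):
    fwd = fwd or (lambda: layer.forward(x, train=True))
    w = rng.normal(size=fwd().shape)

    def loss():
        return float((fwd() * w).sum())

    for p in layer.params():
        p.grad[...] = 0.0
    dx = layer.backward(w.copy())
    errs = []
    for _ in range(n_probe):
        idx = tuple(rng.integers(s) for s in x.shape)
        old = x[idx]
        x[idx] = old + eps
        lp = loss()
        x[idx] = old - eps
        lm = loss()
        x[idx] = old
        errs.append(abs((lp - lm) / (2 * eps) - dx[idx]))
    for p in layer.params():
        for _ in range(n_probe):
            idx = tuple(rng.integers(s) for s in p.value.shape)
            old = p.value[idx]
            p.value[idx] = old + eps
            lp = loss()
            p.value[idx] = old - eps
            lm = loss()
            p.value[idx] = old
            errs.append(abs((lp - lm) / (2 * eps) - p.grad[idx]))
    return max(errs)


class TestLayerGradients:
    def test_conv3x3(self, rng):
        layer = _cast64(Conv2d(3, 5, 3, rng))
        assert _numeric_vs_analytic(layer, rng.normal(size=(2, 3, 9, 11)), rng) < 1e-6

    def test_conv1x1(self, rng):
        layer = _cast64(Conv2d(4, 6, 1, rng))
        assert _numeric_vs_analytic(layer, rng.normal(size=(2, 4, 7, 7)), rng) < 1e-6

    def test_groupnorm(self, rng):
        layer = _cast64(GroupNorm(6, max_groups=3))
        assert _numeric_vs_analytic(layer, rng.normal(size=(2, 6, 7, 7)), rng) < 1e-6

    def test_maxpool_odd_sizes(self, rng):
        layer = MaxPool2()
        assert _numeric_vs_analytic(layer, rng.normal(size=(2, 3, 9, 11)), rng) < 1e-6

    def test_nearest_resize(self, rng):
        layer = NearestResize()
        x = rng.normal(size=(1, 2, 5, 7))
        err = _numeric_vs_analytic(
            layer, x, rng, fwd=lambda: layer.forward(x, 11, 13, train=True)
        )
        assert err < 1e-6


class TestFullNetworkGradient:
    def test_backprop_matches_finite_differences(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        for p in net.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.normal(size=(1, 3, 92, 92))
        ann = rng.integers(0, 3, size=(1, 20, 20))
        net.zero_grad()
        loss, g = masked_loss(net.forward(x, train=True), ann)
        net.backward(g)
        ps = net.params()
        for _ in range(25):
            p = ps[rng.integers(len(ps))]
            idx = tuple(rng.integers(s) for s in p.value.shape)
            eps, old = 1e-6, p.value[idx]
            p.value[idx] = old + eps
            lp = masked_loss(net.forward(x), ann, with_grad=False)[0]
            p.value[idx] = old - eps
            lm = masked_loss(net.forward(x), ann, with_grad=False)[0]
            p.value[idx] = old
            assert abs((lp - lm) / (2 * eps) - p.grad[idx]) < 1e-5

    def test_gradient_step_decreases_loss(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        x = rng.random((1, 3, 92, 92)).astype(np.float32)
        ann = rng.integers(0, 3, size=(1, 20, 20))
        opt = SGDNesterov(net.params(), lr=1e-3, momentum=0.0)
        loss0, g = masked_loss(net.forward(x, train=True), ann)
        net.backward(g)
        opt.step()
        loss1, _ = masked_loss(net.forward(x), ann, with_grad=False)
        assert loss1 < loss0


class TestArchitecture:
    def test_parameter_count_is_1_3_million(self):
        net = build_network(seed=0)
        assert round(net.num_params() / 1e6, 1) == 1.3

    def test_output_is_input_minus_72(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        for size in (92, 100, 131):  # odd sizes must work too
            y = net.forward(rng.random((1, 3, size, size), dtype=np.float32))
            assert y.shape == (1, 2, size - CONTEXT, size - CONTEXT)

    def test_batch_axis(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        y = net.forward(rng.random((2, 3, 92, 92), dtype=np.float32))
        assert y.shape[0] == 2

    def test_parameter_count_invariant_to_input_size(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        n0 = net.num_params()
        net.forward(rng.random((1, 3, 120, 120), dtype=np.float32))
        assert net.num_params() == n0  # fully convolutional

    def test_seeded_build_is_deterministic(self, tiny_net_config):
        a = build_network(tiny_net_config, seed=3)
        b = build_network(tiny_net_config, seed=3)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_he_init_not_saturated(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        logits = net.forward(rng.random((1, 3, 92, 92), dtype=np.float32))
        assert np.isfinite(logits).all()
        mean_fg = float(softmax_fg(logits).mean())
        assert 0.01 < mean_fg < 0.99

    def test_wrong_channel_count_rejected(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        with pytest.raises(ValueError):
            net.forward(rng.random((1, 1, 92, 92), dtype=np.float32))

    def test_too_small_input_rejected(self, tiny_net_config, rng):
        net = UNet(tiny_net_config, rng)
        with pytest.raises(ValueError):
            net.forward(rng.random((1, 3, 60, 60), dtype=np.float32))

    def test_config_geometry_validated(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_size=572, output_size=400)


class TestCheckpoints:
    def test_save_load_round_trip(self, tiny_net_config, rng, tmp_path):
        net = UNet(tiny_net_config, rng)
        x = rng.random((1, 3, 92, 92), dtype=np.float32)
        y0 = net.forward(x)
        p = tmp_path / "ck.npz"
        net.save(p)
        net2 = UNet.load(p)
        assert net2.config == tiny_net_config
        assert np.allclose(net2.forward(x), y0)

    def test_config_mismatch_rejected(self, tiny_net_config, rng, tmp_path):
        net = UNet(tiny_net_config, rng)
        p = tmp_path / "ck.npz"
        net.save(p)
        other = NetworkConfig(down_widths=(4, 8), up_widths=(6,),
                              input_size=92, output_size=20)
        with pytest.raises(ValueError):
            build_network(other, init=str(p))


class TestMaskedLoss:
    def test_perfect_prediction_near_zero(self):
        ann = np.array([[[1, 2], [1, 2]]])
        logits = np.zeros((1, 2, 2, 2), dtype=np.float32)
        fg = ann[0] == 1
        logits[0, 1][fg] = 20.0
        logits[0, 0][~fg] = 20.0
        loss, _ = masked_loss(logits, ann, with_grad=False)
        assert loss < 0.01

    def test_hand_computed_two_pixel_example(self):
        # annotation [fg, bg, undef, undef]; fg probabilities 0.8 and 0.3
        ann = np.array([[[1, 2], [0, 0]]])
        logits = np.zeros((1, 2, 2, 2), dtype=np.float64)
        logits[0, 1, 0, 0] = np.log(0.8 / 0.2)
        logits[0, 1, 0, 1] = np.log(0.3 / 0.7)
        # independent arithmetic: soft dice with eps=1 on annotated pixels
        inter, union = 0.8, (0.8 + 0.3) + 1.0
        dice = (2 * inter + 1.0) / (union + 1.0)
        ce = -(np.log(0.8) + np.log(0.7)) / 2.0
        expected = (1.0 - dice) + ce
        loss, _ = masked_loss(logits, ann, with_grad=False)
        assert loss == pytest.approx(expected, rel=1e-6)

    def test_undefined_pixels_carry_no_gradient(self, rng):
        ann = rng.integers(0, 3, size=(1, 6, 6))
        logits = rng.normal(size=(1, 2, 6, 6))
        _, g = masked_loss(logits, ann)
        undef = ann[0] == 0
        assert np.all(g[0, :, undef] == 0.0)

    def test_empty_annotation_contributes_zero(self, rng):
        logits = rng.normal(size=(1, 2, 4, 4))
        loss, g = masked_loss(logits, np.zeros((1, 4, 4), dtype=int))
        assert loss == 0.0
        assert np.all(g == 0.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            masked_loss(rng.normal(size=(1, 2, 4, 4)),
                        np.zeros((1, 5, 5), dtype=int))
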