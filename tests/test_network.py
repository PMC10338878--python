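"""LDSE-NET architecture: dense connectivity, SE arithmetic, gradients."""

import math

import numpy as np
import pytest

from ldsefocus.nn.layers import AvgPool2d, BatchNorm2d, Conv2d, MaxPool2d
from ldsefocus.nn.network import (
    DenseBlock,
    LDSENet,
    LDSENetConfig,
    SqueezeExcitation,
    Transition,
    excitation,
    model_size_bytes,
    scale,
    squeeze,
)


class TestSqueeze:
    def test_constant_channel(self):
        u = np.full((3, 4, 5), 2.5)
        assert np.allclose(squeeze(u), 2.5)

    def test_small_mean(self):
        u = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert squeeze(u)[0] == pytest.approx(2.5)

    def test_linearity_across_channels(self):
        # sum_m Z_m equals the spatial mean of the channel-summed map
        rng = np.random.default_rng(0)
        u = rng.random((4, 6, 6))
        assert np.sum(squeeze(u)) == pytest.approx(u.sum(axis=0).mean(), rel=1e-12)

    def test_batched_input(self):
        rng = np.random.default_rng(1)
        u = rng.random((2, 3, 4, 4))
        z = squeeze(u)
        assert z.shape == (2, 3)
        assert np.allclose(z, u.mean(axis=(2, 3)))


class TestExcitation:
    def test_zero_input_gives_zero_gate(self):
        W = np.eye(2)
        assert np.allclose(excitation(np.zeros(2), W, W), 0.0)

    def test_identity_weights_hand_value(self):
        # S = tanh(relu([1, 0])) = (tanh(1), 0)
        W = np.eye(2)
        s = excitation(np.array([1.0, 0.0]), W, W)
        assert s[0] == pytest.approx(math.tanh(1.0), abs=1e-12)
        assert s[1] == 0.0

    def test_gate_bounded_and_monotone(self):
        W = np.eye(3)
        zs = np.linspace(0, 10, 20)
        gates = [excitation(np.array([z, 0, 0]), W, W)[0] for z in zs]
        assert all(-1 < g < 1 for g in gates)
        assert all(b >= a for a, b in zip(gates, gates[1:]))

    def test_sigmoid_variant(self):
        W = np.eye(2)
        s = excitation(np.zeros(2), W, W, gate="sigmoid")
        assert np.allclose(s, 0.5)

    def test_bottleneck_shapes(self):
        for c, r in [(8, 2), (45, 4), (7, 16)]:
            se = SqueezeExcitation(c, r, np.random.default_rng(0))
            assert se.fc1.weight.value.shape == (math.ceil(c / r), c)
            assert se.fc2.weight.value.shape == (c, math.ceil(c / r))


class TestScale:
    def test_unit_gates_identity(self):
        rng = np.random.default_rng(0)
        u = rng.random((3, 4, 4))
        assert np.array_equal(scale(u, np.ones(3)), u)

    def test_zero_gates_zero_map(self):
        u = np.ones((2, 3, 3))
        assert np.all(scale(u, np.zeros(2)) == 0)

    def test_negative_gate_flips_channel_sign(self):
        u = np.ones((2, 2, 2))
        out = scale(u, np.array([-0.5, 1.0]))
        assert np.all(out[0] == -0.5) and np.all(out[1] == 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scale(np.ones((2, 3, 3)), np.ones(3))


class TestDenseBlock:
    def test_channel_concatenation_arithmetic(self):
        rng = np.random.default_rng(0)
        for c0, n_layers, k in [(8, 2, 4), (16, 4, 12), (5, 3, 7)]:
            block = DenseBlock(c0, n_layers, k, rng, "b")
            x = np.random.default_rng(1).random((2, c0, 8, 8)).astype(np.float32)
            out = block(x, train=True)
            assert out.shape[1] == c0 + n_layers * k
            # layer L sees C0 + (L-1)*k channels
            for i, layer in enumerate(block.layers):
                assert layer.conv.in_ch == c0 + i * k

    def test_zero_conv_zero_output_channels(self):
        rng = np.random.default_rng(0)
        block = DenseBlock(4, 1, 2, rng, "b")
        block.layers[0].conv.weight.value[...] = 0.0
        x = np.random.default_rng(1).random((1, 4, 6, 6)).astype(np.float32)
        out = block(x, train=True)
        assert np.all(out[:, 4:] == 0)

    def test_dense_connectivity_information_path(self):
        """Perturbing an early layer's output changes every later layer's input."""
        rng = np.random.default_rng(0)
        block = DenseBlock(6, 3, 4, rng, "b")
        x = np.random.default_rng(2).random((1, 6, 8, 8)).astype(np.float32)

        layer_inputs = []
        h = x
        for layer in block.layers:
            layer_inputs.append(h)
            h = np.concatenate([h, layer(h, train=True)], axis=1)

        # perturb layer 0's conv and re-run
        block.layers[0].conv.weight.value += 0.5
        h = x
        perturbed_inputs = []
        for layer in block.layers:
            perturbed_inputs.append(h)
            h = np.concatenate([h, layer(h, train=True)], axis=1)

        for before, after in zip(layer_inputs[1:], perturbed_inputs[1:]):
            assert not np.allclose(before, after)


class TestTransition:
    def test_spatial_halving_and_channel_reduction(self):
        rng = np.random.default_rng(0)
        t = Transition(64, 0.5, rng, "t")
        x = np.random.default_rng(1).random((2, 64, 56, 56)).astype(np.float32)
        out = t(x, train=True)
        assert out.shape == (2, 32, 28, 28)

    def test_constant_map_forward_oracle(self):
        """Hand-computed forward on a constant 2x2 map: batch-norm maps a
        constant to beta, tanh(0)=0 with identity gamma/beta, the 1x1 conv
        scales it, and 2x2 average pooling preserves a constant."""
        rng = np.random.default_rng(0)
        t = Transition(1, 1.0, rng, "t")
        t.conv.weight.value[...] = 2.0
        t.bn.beta.value[...] = 0.3
        x = np.full((1, 1, 2, 2), 7.0, dtype=np.float32)
        out = t(x, train=True)
        # constant input: xhat = 0 -> bn out = beta -> tanh(0.3) -> *2 -> pooled
        expected = 2.0 * np.tanh(0.3)
        assert out.shape == (1, 1, 1, 1)
        assert out[0, 0, 0, 0] == pytest.approx(expected, rel=1e-5)


class TestLDSENet:
    def test_default_reaches_seven_by_seven_head(self):
        net = LDSENet(LDSENetConfig(), seed=0)
        x = np.zeros((1, 3, 224, 224), dtype=np.float32)
        net.forward(x, train=False)
        assert net._head_spatial == (7, 7)

    def test_forward_deterministic(self, tiny_net):
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        a = tiny_net.forward(x, train=False)
        b = tiny_net.forward(x, train=False)
        assert np.array_equal(a, b)

    def test_batch_consistency(self, tiny_net):
        x = np.random.default_rng(3).random((4, 1, 32, 32)).astype(np.float32)
        batch = tiny_net.forward(x, train=False)
        singles = np.array([tiny_net.forward(x[i : i + 1], train=False)[0] for i in range(4)])
        assert np.allclose(batch, singles, atol=1e-5)

    def test_wrong_input_shape_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="tiles"):
            tiny_net.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError, match="input"):
            tiny_net.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))

    def test_finite_output_and_gradients(self, tiny_net):
        rng = np.random.default_rng(5)
        x = rng.random((3, 1, 32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, 3).astype(np.float32)
        tiny_net.zero_grad()
        pred = tiny_net.forward(x, train=True)
        assert np.all(np.isfinite(pred))
        tiny_net.backward(2.0 / 3 * (pred - y))
        for p in tiny_net.parameters():
            assert np.all(np.isfinite(p.grad)), p.name

    def test_predict_um_inverse_scaling(self, tiny_net_config):
        net = LDSENet(tiny_net_config, seed=1)
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        raw = net.forward(x, train=False)
        um = net.predict_um(x)
        assert np.allclose(um, raw * tiny_net_config.z_half_range_um, atol=1e-6)

    def test_checkpoint_roundtrip(self, tiny_net, tmp_path):
        x = np.random.default_rng(1).random((2, 1, 32, 32)).astype(np.float32)
        # touch batch-norm running stats so buffers are non-trivial
        tiny_net.forward(x, train=True)
        before = tiny_net.predict_um(x)
        path = tmp_path / "ckpt.npz"
        tiny_net.save(path)
        loaded = LDSENet.load(path)
        assert np.array_equal(loaded.predict_um(x), before)
        assert loaded.config == tiny_net.config


class TestModelSize:
    def test_default_within_lightweight_budget(self):
        assert model_size_bytes(LDSENetConfig()) <= 480 * 1024

    def test_growth_rate_monotonicity(self):
        small = model_size_bytes(LDSENetConfig(growth_rate_k=12))
        big = model_size_bytes(LDSENetConfig(growth_rate_k=24))
        assert big > small

    def test_matches_per_layer_enumeration(self, tiny_net_config):
        """Brute-force parameter count over the architecture layout."""
        cfg = tiny_net_config
        expected = 0
        expected += cfg.stem_channels * cfg.input_channels * 49  # stem conv 7x7
        expected += 2 * cfg.stem_channels  # stem bn
        c = cfg.stem_channels
        for n_layers in cfg.layers_per_block:
            for i in range(n_layers):
                cin = c + i * cfg.growth_rate_k
                expected += 2 * cin  # dense-layer bn
                expected += cfg.growth_rate_k * cin * 9  # 3x3 conv
            c = c + n_layers * cfg.growth_rate_k
            expected += 2 * c  # transition bn
            cout = max(1, math.floor(c * cfg.transition_reduction))
            expected += cout * c  # 1x1 conv
            c = cout
        bottleneck = math.ceil(c / cfg.se_reduction_r)
        expected += bottleneck * c + bottleneck  # se fc1
        expected += c * bottleneck + c  # se fc2
        expected += c + 1  # head
        assert model_size_bytes(cfg) == 4 * expected


class TestGradientCorrectness:
    def test_backprop_matches_finite_differences(self, tiny_net_config):
        """Central finite differences vs. analytic gradients, float64."""
        net = LDSENet(tiny_net_config, seed=3, dtype=np.float64)
        rng = np.random.default_rng(7)
        x = rng.random((3, 1, 32, 32))
        y = rng.uniform(-1, 1, 3)

        def loss():
            return float(np.mean((net.forward(x, train=True) - y) ** 2))

        net.zero_grad()
        pred = net.forward(x, train=True)
        net.backward(2.0 / len(y) * (pred - y))

        eps = 1e-5
        check_rng = np.random.default_rng(0)
        worst = 0.0
        for p in net.parameters():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for ix in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[ix]
                flat[ix] = orig + eps
                lp = loss()
                flat[ix] = orig - eps
                lm = loss()
                flat[ix] = orig
                fd = (lp - lm) / (2 * eps)
                rel = abs(fd - gflat[ix]) / max(abs(fd), abs(gflat[ix]), 1e-6)
                worst = max(worst, rel)
        assert worst < 1e-4
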