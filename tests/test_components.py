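"""The three architectural mechanisms against independent scalar oracles.

All oracle computations use 1x1 kernels on tiny maps so the network math
reduces to per-pixel arithmetic that can be written out by hand, fully
independent of the autograd implementation they check.
"""

import numpy as np
import pytest

from attr2unet.components import (
    RRCB,
    AttentionGate,
    RecurrentConvLayer,
    iterate_residual,
    unrolled_residual_input,
)
from attr2unet.nn.autograd import Tensor


def _rng():
    return np.random.default_rng(42)


def _set_eval_bn_identity(layer):
    """Freeze every batch norm in `layer` to the identity transform."""
    from attr2unet.nn.modules import BatchNorm2d

    for m in layer.modules():
        if isinstance(m, BatchNorm2d):
            m.set_running_stats(np.zeros(m.num_features), np.ones(m.num_features))


# ---------------------------------------------------------------------------
# Attention gate
# ---------------------------------------------------------------------------


class TestAttentionGate:
    def test_zero_weights_give_half_coefficients(self):
        gate = AttentionGate(3, 3, _rng(), dtype=np.float64)
        for p in gate.parameters():
            p.data[...] = 0.0
        x_e = Tensor(np.random.default_rng(0).random((2, 3, 4, 4)))
        x_d = Tensor(np.random.default_rng(1).random((2, 3, 4, 4)))
        out = gate(x_e, x_d)
        assert np.allclose(out.coefficients.data, 0.5)
        assert np.allclose(out.gated.data, 0.5 * x_e.data)

    def test_large_negative_bias_suppresses_everything(self):
        gate = AttentionGate(2, 2, _rng(), dtype=np.float64)
        for p in gate.parameters():
            p.data[...] = 0.0
        gate.psi.bias.data[...] = -1000.0
        x_e = Tensor(np.ones((1, 2, 3, 3)))
        out = gate(x_e, Tensor(np.ones((1, 2, 3, 3))))
        assert np.all(out.coefficients.data < 1e-12)
        assert np.all(np.abs(out.gated.data) < 1e-12)

    def test_matches_per_pixel_scalar_oracle(self):
        """Random 1-channel 2x2 inputs with 1x1 weights: the gate must equal
        sigmoid(psi*relu(we*xe + wd*xd + bl) + bm) computed pixel by pixel."""
        rng = np.random.default_rng(5)
        gate = AttentionGate(1, 1, _rng(), inter_channels=1, dtype=np.float64)
        we = rng.normal()
        wd = rng.normal()
        bl = rng.normal()
        psi = rng.normal()
        bm = rng.normal()
        gate.conv_e.weight.data[...] = we
        gate.conv_e.bias.data[...] = bl
        gate.conv_d.weight.data[...] = wd
        gate.psi.weight.data[...] = psi
        gate.psi.bias.data[...] = bm
        x_e = rng.random((1, 1, 2, 2))
        x_d = rng.random((1, 1, 2, 2))
        out = gate(Tensor(x_e), Tensor(x_d))
        for i in range(2):
            for j in range(2):
                lam = we * x_e[0, 0, i, j] + wd * x_d[0, 0, i, j] + bl
                mu = psi * max(lam, 0.0) + bm
                alpha = 1.0 / (1.0 + np.exp(-mu))
                assert out.coefficients.data[0, 0, i, j] == pytest.approx(alpha, abs=1e-6)
                assert out.gated.data[0, 0, i, j] == pytest.approx(alpha * x_e[0, 0, i, j], abs=1e-6)

    def test_coefficients_strictly_in_unit_interval_and_gated_bounded(self):
        gate = AttentionGate(4, 4, _rng())
        rng = np.random.default_rng(9)
        x_e = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32) * 10)
        x_d = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32) * 10)
        out = gate(x_e, x_d)
        a = out.coefficients.data
        assert np.all(a > 0.0) and np.all(a < 1.0)
        assert np.all(np.abs(out.gated.data) <= np.abs(x_e.data) + 1e-12)

    def test_spatial_and_batch_mismatch_raise(self):
        gate = AttentionGate(1, 1, _rng())
        with pytest.raises(ValueError, match="spatial"):
            gate(Tensor(np.zeros((1, 1, 4, 4), np.float32)), Tensor(np.zeros((1, 1, 2, 2), np.float32)))
        with pytest.raises(ValueError, match="batch"):
            gate(Tensor(np.zeros((1, 1, 4, 4), np.float32)), Tensor(np.zeros((2, 1, 4, 4), np.float32)))


# ---------------------------------------------------------------------------
# Recurrent convolutional layer
# ---------------------------------------------------------------------------


class TestRecurrentConvLayer:
    def _identity_bn_layer(self, t, seed=3):
        layer = RecurrentConvLayer(1, 1, t=t, rng=np.random.default_rng(seed), kernel_size=1, dtype=np.float64)
        _set_eval_bn_identity(layer)
        layer.eval()
        return layer

    def test_t1_equals_plain_conv_bn_relu(self):
        layer = self._identity_bn_layer(t=1)
        x = np.random.default_rng(0).normal(size=(1, 1, 3, 3))
        out = layer(Tensor(x))
        wf = layer.conv_f.weight.data.item()
        b = layer.conv_f.bias.data.item()
        assert np.allclose(out.data, np.maximum(wf * x + b, 0.0))

    def test_zero_recurrent_weights_freeze_iteration(self):
        layer3 = self._identity_bn_layer(t=3)
        layer3.conv_r.weight.data[...] = 0.0
        layer1 = self._identity_bn_layer(t=1)
        layer1.conv_f.weight.data[...] = layer3.conv_f.weight.data
        layer1.conv_f.bias.data[...] = layer3.conv_f.bias.data
        x = np.random.default_rng(1).normal(size=(2, 1, 2, 2))
        assert np.allclose(layer3(Tensor(x)).data, layer1(Tensor(x)).data)

    def test_matches_hand_unrolled_three_step_oracle(self):
        """t=3, 1x1 kernel, identity eval BN: O(k) = relu(wf*x + b + wr*O(k-1))."""
        layer = self._identity_bn_layer(t=3)
        wf = layer.conv_f.weight.data.item()
        b = layer.conv_f.bias.data.item()
        wr = layer.conv_r.weight.data.item()
        x = np.random.default_rng(2).normal(size=(1, 1, 2, 2))
        o = np.maximum(wf * x + b, 0.0)
        for _ in range(2):
            o = np.maximum(wf * x + b + wr * o, 0.0)
        assert np.allclose(layer(Tensor(x)).data, o, atol=1e-6)

    def test_output_nonnegative_and_shape_preserved(self):
        layer = RecurrentConvLayer(2, 5, t=2, rng=_rng())
        x = Tensor(np.random.default_rng(3).normal(size=(2, 2, 7, 9)).astype(np.float32))
        out = layer(x)
        assert out.data.shape == (2, 5, 7, 9)
        assert np.all(out.data >= 0.0)

    def test_channel_mismatch_raises(self):
        layer = RecurrentConvLayer(2, 2, t=1, rng=_rng())
        with pytest.raises(ValueError, match="channel"):
            layer(Tensor(np.zeros((1, 3, 4, 4), np.float32)))

    def test_invalid_t_rejected(self):
        with pytest.raises(ValueError):
            RecurrentConvLayer(1, 1, t=0, rng=_rng())


# ---------------------------------------------------------------------------
# Recurrent residual convolutional block
# ---------------------------------------------------------------------------


class TestRRCB:
    def test_zero_body_reduces_to_shortcut(self):
        block = RRCB(2, 3, t=2, rng=_rng(), dtype=np.float64)
        _set_eval_bn_identity(block)
        block.eval()
        for name, p in block.named_parameters():
            if not name.startswith("shortcut"):
                p.data[...] = 0.0
        x = np.random.default_rng(0).normal(size=(1, 2, 4, 4))
        out = block(Tensor(x))
        w = block.shortcut.weight.data[:, :, 0, 0]
        expected = np.einsum("oc,nchw->nohw", w, x) + block.shortcut.bias.data.reshape(1, -1, 1, 1)
        assert np.allclose(out.data, expected)

    def test_zero_modulating_scalar_keeps_body_only(self):
        block = RRCB(1, 1, t=1, rng=_rng(), modulating_scalar=0.0, dtype=np.float64)
        _set_eval_bn_identity(block)
        block.eval()
        x = np.random.default_rng(1).normal(size=(1, 1, 3, 3))
        pre = block.shortcut(Tensor(x))
        body = block.layer2(block.layer1(pre))
        assert np.allclose(block(Tensor(x)).data, body.data)

    def test_matches_composed_rcl_oracle(self):
        """Random 1-channel 1x1-kernel instance: block output must equal
        alpha*shortcut + RCL(RCL(shortcut)) computed with scalar arithmetic."""
        rng = np.random.default_rng(11)
        block = RRCB(1, 1, t=2, rng=np.random.default_rng(8), dtype=np.float64)
        # Force 1x1 behaviour by zeroing off-centre 3x3 taps.
        for conv in (block.layer1.conv_f, block.layer1.conv_r, block.layer2.conv_f, block.layer2.conv_r):
            w = np.zeros_like(conv.weight.data)
            w[0, 0, 1, 1] = rng.normal()
            conv.weight.data = w
        _set_eval_bn_identity(block)
        block.eval()
        x = rng.normal(size=(1, 1, 2, 2))
        ws = block.shortcut.weight.data.item()
        bs = block.shortcut.bias.data.item()
        pre = ws * x + bs

        def rcl(v, layer):
            wf = layer.conv_f.weight.data[0, 0, 1, 1]
            b = layer.conv_f.bias.data.item()
            wr = layer.conv_r.weight.data[0, 0, 1, 1]
            o = np.maximum(wf * v + b, 0.0)
            o = np.maximum(wf * v + b + wr * o, 0.0)
            return o

        expected = 1.0 * pre + rcl(rcl(pre, block.layer1), block.layer2)
        assert np.allclose(block(Tensor(x)).data, expected, atol=1e-6)

    def test_gradient_flows_through_shortcut_when_body_zeroed(self):
        from attr2unet.nn import autograd as ag
        from attr2unet.nn.autograd import Parameter

        block = RRCB(1, 2, t=1, rng=_rng(), dtype=np.float64)
        _set_eval_bn_identity(block)
        block.eval()
        for name, p in block.named_parameters():
            if not name.startswith("shortcut"):
                p.data[...] = 0.0
        x = Parameter(np.random.default_rng(4).normal(size=(1, 1, 2, 2)))
        out = ag.sum_all(block(x))
        out.backward()
        # d(sum of outputs)/dx = sum over output channels of shortcut weights
        expected = block.shortcut.weight.data.sum()
        assert np.allclose(x.grad, expected)

    def test_spatial_dims_preserved_for_odd_sizes(self):
        block = RRCB(1, 2, t=2, rng=_rng())
        out = block(Tensor(np.random.default_rng(0).random((1, 1, 5, 7)).astype(np.float32)))
        assert out.data.shape == (1, 2, 5, 7)


# ---------------------------------------------------------------------------
# Closed-form residual expansion
# ---------------------------------------------------------------------------


class TestResidualExpansion:
    def test_identity_when_alphas_one_and_bodies_zero(self):
        x = np.array([[2.5]])
        layers = [(1.0, lambda v: 0.0 * v)] * 4
        assert np.allclose(unrolled_residual_input(5, 1, x, layers), x)

    def test_base_case_is_single_residual_step(self):
        rng = np.random.default_rng(0)
        a, w, b = rng.normal(size=3)
        f = lambda v: np.maximum(w * v + b, 0.0)
        x = rng.normal(size=(1, 1, 1, 1))
        assert np.allclose(unrolled_residual_input(2, 1, x, [(a, f)]), a * x + f(x))

    def test_closed_form_equals_sequential_iteration(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 1, 1, 1))
        layers = []
        for _ in range(3):
            a, w, b = rng.normal(size=3)
            layers.append((a, (lambda w, b: lambda v: np.maximum(w * v + b, 0.0))(w, b)))
        closed = unrolled_residual_input(4, 1, x, layers)
        sequential = iterate_residual(x, layers)
        assert np.allclose(closed, sequential, atol=1e-9)

    def test_invalid_layer_order_raises(self):
        with pytest.raises(ValueError):
            unrolled_residual_input(1, 1, np.zeros((1,)), [])
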