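"""Fast-normalised fusion and the dual-pathway neck."""

import numpy as np
import pytest

from wfpn import nn
from wfpn.backbone import TinyBackbone
from wfpn.neck import (
    FusionNode,
    TopNode,
    WeightedPyramidNeck,
    bottom_up_step,
    fast_normalized_fusion,
    top_down_step,
    top_node_init,
)
from wfpn.nn import Tensor, functional as F
from wfpn.nn.functional import cross_entropy

from conftest import make_tiny_model


def const_map(value, shape=(1, 2, 3, 3)):
    return Tensor(np.full(shape, float(value)))


def make_node(weights, epsilon=1e-4, **kwargs):
    nn.manual_seed(0)
    node = FusionNode(num_inputs=len(weights), epsilon=epsilon, smoothing=False, **kwargs)
    node.raw_weights.data = np.array(weights, dtype=float)
    return node


class TestFastNormalizedFusion:
    def test_unit_weights_on_unit_inputs(self):
        node = make_node([1.0, 1.0], epsilon=1e-4)
        out = fast_normalized_fusion([const_map(1), const_map(1)], node)
        np.testing.assert_allclose(out.numpy(), 2.0 / 2.0001, atol=1e-12)

    def test_zero_weight_input_is_ignored(self):
        node = make_node([0.0, 2.0])
        rng = np.random.default_rng(0)
        other = Tensor(rng.normal(size=(1, 2, 3, 3)))
        out1 = fast_normalized_fusion([const_map(5), other], node)
        out2 = fast_normalized_fusion([const_map(-7), other], node)
        np.testing.assert_array_equal(out1.numpy(), out2.numpy())

    def test_exact_weighted_mean_with_zero_epsilon(self):
        node = make_node([3.0, 1.0], epsilon=0.0)
        out = fast_normalized_fusion([const_map(1), const_map(5)], node)
        np.testing.assert_allclose(out.numpy(), 2.0, atol=1e-12)

    def test_coefficients_sum_below_one(self):
        for weights in ([1, 1], [0.2, 5.0], [3, 3]):
            node = make_node(weights)
            c = node.fusion_coefficients().numpy()
            assert (c >= 0).all() and (c < 1).all()
            total = np.sum(np.maximum(weights, 0))
            assert c.sum() == pytest.approx(total / (total + node.epsilon), abs=1e-12)

    def test_raising_one_weight_raises_its_coefficient_only(self):
        base = make_node([1.0, 1.0, 1.0])
        more = make_node([2.0, 1.0, 1.0])
        c0, c1 = base.fusion_coefficients().numpy(), more.fusion_coefficients().numpy()
        assert c1[0] > c0[0]
        assert (c1[1:] < c0[1:]).all()

    def test_negative_raw_weights_are_rectified(self):
        node = make_node([-3.0, 1.0])
        c = node.fusion_coefficients().numpy()
        assert c[0] == 0.0 and c[1] > 0

    def test_shape_and_arity_contracts(self):
        node = make_node([1.0, 1.0])
        with pytest.raises(ValueError, match="share a shape"):
            fast_normalized_fusion([const_map(1), const_map(1, (1, 2, 4, 4))], node)
        with pytest.raises(ValueError, match="expects 2 inputs"):
            fast_normalized_fusion([const_map(1)], node)


class TestTopDownStep:
    def test_shape_contract_from_b5(self):
        nn.manual_seed(0)
        node = FusionNode(in_channels=2048, channels=256)
        b5 = Tensor(np.random.default_rng(0).normal(size=(2, 2048, 7, 7)))
        f6 = Tensor(np.random.default_rng(1).normal(size=(2, 256, 1, 1)))
        assert top_down_step(b5, f6, node).shape == (2, 256, 7, 7)

    def test_zero_weight_above_reduces_to_projection(self):
        node = make_node([1.0, 0.0], in_channels=4, channels=4)
        rng = np.random.default_rng(2)
        b = Tensor(rng.normal(size=(1, 4, 4, 4)))
        f_above = Tensor(rng.normal(size=(1, 4, 2, 2)))
        out = top_down_step(b, f_above, node)
        shrink = 1.0 / (1.0 + node.epsilon)
        np.testing.assert_allclose(out.numpy(), node.project(b).numpy() * shrink, atol=1e-12)

    def test_single_pixel_scalar_oracle(self):
        # identity 1x1 projection, no smoothing, eps 0 -> plain mean of the inputs
        node = make_node([1.0, 1.0], epsilon=0.0, in_channels=1, channels=1)
        node.projection_conv.weight.data = np.ones((1, 1, 1, 1))
        node.projection_conv.bias.data = np.zeros(1)
        b = Tensor(np.full((1, 1, 1, 1), 3.0))
        f_above = Tensor(np.full((1, 1, 1, 1), 7.0))
        out = top_down_step(b, f_above, node)
        assert out.numpy().item() == pytest.approx((3.0 + 7.0) / 2.0, abs=1e-12)

    def test_rejects_finer_upper_map(self):
        node = make_node([1.0, 1.0], in_channels=4, channels=4)
        b = const_map(0, (1, 4, 2, 2))
        f_above = const_map(0, (1, 4, 5, 5))
        with pytest.raises(ValueError, match="coarser"):
            top_down_step(b, f_above, node)


class TestTopNode:
    def test_constant_map_doubles_before_projection(self):
        nn.manual_seed(0)
        node = TopNode(4, 4)
        node.conv.weight.data = np.eye(4).reshape(4, 4, 1, 1)
        node.conv.bias.data = np.zeros(4)
        out = top_node_init(const_map(1.5, (2, 4, 4, 4)), node)
        np.testing.assert_allclose(out.numpy(), 3.0, atol=1e-12)

    def test_shape_contract(self):
        nn.manual_seed(0)
        node = TopNode(32, 256)
        out = top_node_init(Tensor(np.random.default_rng(0).normal(size=(2, 32, 4, 4))), node)
        assert out.shape == (2, 256, 1, 1)

    def test_pooling_against_brute_force(self):
        # a spiked map: max pool returns the spike, avg pool the loop mean
        x = np.random.default_rng(3).normal(size=(1, 3, 4, 4))
        x[0, 1, 2, 3] = 50.0
        avg = F.global_avg_pool2d(Tensor(x)).numpy()
        mx = F.global_max_pool2d(Tensor(x)).numpy()
        for c in range(3):
            total, top = 0.0, -np.inf
            for i in range(4):
                for j in range(4):
                    total += x[0, c, i, j]
                    top = max(top, x[0, c, i, j])
            assert avg[0, c, 0, 0] == pytest.approx(total / 16, abs=1e-12)
            assert mx[0, c, 0, 0] == pytest.approx(top, abs=1e-12)
        assert mx[0, 1, 0, 0] == 50.0


class TestBottomUpStep:
    def test_shape_contract(self):
        nn.manual_seed(0)
        node = FusionNode(channels=256)
        f5 = Tensor(np.random.default_rng(0).normal(size=(2, 256, 7, 7)))
        p4 = Tensor(np.random.default_rng(1).normal(size=(2, 256, 14, 14)))
        assert bottom_up_step(f5, p4, node).shape == (2, 256, 7, 7)

    def test_zero_weight_below_reduces_to_refined_map(self):
        node = make_node([1.0, 0.0])
        rng = np.random.default_rng(2)
        f = Tensor(rng.normal(size=(1, 2, 3, 3)))
        p_below = Tensor(rng.normal(size=(1, 2, 6, 6)))
        out = bottom_up_step(f, p_below, node)
        np.testing.assert_allclose(out.numpy(), f.numpy() / (1.0 + node.epsilon), atol=1e-12)

    def test_downsample_is_window_average(self):
        x = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        out = F.adaptive_avg_pool2d(x, 1).numpy()
        assert out.item() == pytest.approx(2.5, abs=1e-12)

    def test_rejects_coarser_lower_map(self):
        node = make_node([1.0, 1.0])
        with pytest.raises(ValueError, match="finer"):
            bottom_up_step(const_map(0, (1, 2, 4, 4)), const_map(0, (1, 2, 2, 2)), node)


class TestNeckContracts:
    @pytest.mark.parametrize("size", [64, 96])
    def test_all_maps_have_neck_width_and_expected_resolution(self, size):
        nn.manual_seed(0)
        bb = TinyBackbone().eval()
        neck = WeightedPyramidNeck(dict(bb.out_channels), channels=32).eval()
        x = Tensor(np.random.default_rng(0).normal(size=(1, 3, size, size)))
        with nn.no_grad():
            h = bb(x)
            out = neck(h)
        for group in (out.top_down, out.refined, out.bottom_up):
            assert all(t.shape[1] == 32 for t in group.values())
        assert out.top_down[6].shape[2:] == (1, 1)
        assert out.bottom_up[6].shape[2:] == (1, 1)
        assert out.top_down[4].shape[2:] == h[4].tensor.shape[2:]
        assert out.bottom_up[5].shape[2:] == h[5].tensor.shape[2:]

    def test_lowest_bottom_up_map_is_the_refined_map(self):
        nn.manual_seed(0)
        bb = TinyBackbone().eval()
        neck = WeightedPyramidNeck(dict(bb.out_channels), channels=32).eval()
        x = Tensor(np.random.default_rng(1).normal(size=(1, 3, 64, 64)))
        with nn.no_grad():
            out = neck(bb(x))
        np.testing.assert_array_equal(out.bottom_up[4].numpy(), out.refined[4].numpy())
        # perturbing the deeper bottom-up nodes cannot reach P4
        neck.bu_nodes[5].raw_weights.data[:] = [7.0, 0.1]
        neck.bu_nodes[6].raw_weights.data[:] = [0.3, 9.0]
        with nn.no_grad():
            out2 = neck(bb(x))
        np.testing.assert_array_equal(out2.bottom_up[4].numpy(), out.bottom_up[4].numpy())

    def test_every_fusion_weight_receives_gradient(self):
        model = make_tiny_model()
        x = Tensor(np.random.default_rng(2).normal(size=(2, 3, 64, 64)))
        loss = cross_entropy(model(x), np.array([0, 1]))
        model.zero_grad()
        loss.backward()
        weight_params = {
            name: p for name, p in model.named_parameters() if "raw_weights" in name
        }
        assert len(weight_params) == 5  # 2 top-down + 2 bottom-up + ensemble
        for name, p in weight_params.items():
            assert p.grad is not None, name
            assert np.abs(p.grad).max() > 0, name
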