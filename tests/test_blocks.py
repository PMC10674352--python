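"""ECA, ASPC, ASPP and receptive-field contracts."""

import numpy as np
import pytest

from redtidenet.blocks import (
    ASPC2,
    ASPC3,
    ASPCBlock,
    ASPCConfig,
    ASPPBlock,
    ECA,
    ECAConfig,
    aspc_branch_widths,
    aspc_forward,
    aspp_forward,
    eca_apply,
    eca_kernel_size,
    receptive_field,
    receptive_field_empirical,
)
from redtidenet.nn import Conv2d
from redtidenet.nn.autograd import Tensor, global_avg_pool, expand_hw


class TestECA:
    def test_zero_conv_weights_scale_everything_by_half(self, rng):
        eca = ECA(channels=7)
        eca.weight.data[:] = 0.0  # sigmoid(0) = 0.5 for every channel
        x = rng.standard_normal((4, 4, 7)).astype(np.float32)
        np.testing.assert_allclose(eca_apply(x, eca), 0.5 * x, rtol=1e-6)

    def test_tiny_tensor_matches_pool_conv_sigmoid_oracle(self, rng):
        eca = ECA(channels=3, config=ECAConfig(kernel_size=3))
        eca.weight.data[:] = [0.25, -0.5, 1.0]
        x = rng.standard_normal((2, 2, 3)).astype(np.float32)
        out = eca_apply(x, eca)
        # independent brute-force chain on the same tiny tensor
        desc = x.mean(axis=(0, 1))
        padded = np.concatenate([[0.0], desc, [0.0]])
        conv = np.array([padded[i : i + 3] @ eca.weight.data for i in range(3)])
        scales = 1.0 / (1.0 + np.exp(-conv))
        np.testing.assert_allclose(out, x * scales, rtol=1e-6, atol=1e-6)
        assert np.all(scales > 0) and np.all(scales < 1)

    def test_spatial_shape_preserved(self, rng):
        eca = ECA(channels=7)
        x = rng.standard_normal((32, 32, 7)).astype(np.float32)
        assert eca_apply(x, eca).shape == (32, 32, 7)

    def test_output_is_input_times_frozen_scales(self, rng):
        """With the scale vector frozen, attention is linear in the input."""
        eca = ECA(channels=5)
        x = rng.standard_normal((1, 5, 6, 6)).astype(np.float32)
        s = eca.scales(Tensor(x)).data[0]
        out = eca(Tensor(x)).data
        np.testing.assert_allclose(out, x * s[None, :, None, None], rtol=1e-6)
        # and commutes with spatial cropping at fixed scales
        np.testing.assert_allclose(out[..., 1:4, 2:5], (x * s[None, :, None, None])[..., 1:4, 2:5])

    @pytest.mark.parametrize("C,expected", [(64, 3), (7, 1), (256, 5), (2, 1), (1024, 5)])
    def test_adaptive_kernel_size_rule(self, C, expected):
        assert eca_kernel_size(C) == expected

    def test_even_explicit_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ECAConfig(kernel_size=4)


class TestASPC:
    def test_preset_partitions(self):
        assert aspc_branch_widths(ASPC3.channel_fractions, 64) == (32, 16, 16)
        assert aspc_branch_widths(ASPC2.channel_fractions, 64) == (32, 32)

    @pytest.mark.parametrize("config", [ASPC3, ASPC2], ids=["aspc3", "aspc2"])
    def test_widths_sum_exactly_for_all_usable_widths(self, config):
        for c_out in range(len(config.dilations), 129):
            widths = aspc_branch_widths(config.channel_fractions, c_out)
            assert sum(widths) == c_out
            assert all(w >= 1 for w in widths)

    @pytest.mark.parametrize("size", [8, 15, 32, 64])
    @pytest.mark.parametrize("config", [ASPC3, ASPC2], ids=["aspc3", "aspc2"])
    def test_spatial_shape_preserved(self, rng, size, config):
        block = ASPCBlock(7, 12, config, rng=np.random.default_rng(0))
        x = rng.standard_normal((size, size, 7)).astype(np.float32)
        assert aspc_forward(x, block).shape == (size, size, 12)

    def test_mismatched_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ASPCConfig(dilations=(1, 2), channel_fractions=(0.5, 0.25))
        with pytest.raises(ValueError, match="align"):
            ASPCConfig(dilations=(1, 2, 3), channel_fractions=(0.5, 0.5))


class TestASPP:
    def test_output_shape(self, rng):
        block = ASPPBlock(8, 10, rng=np.random.default_rng(0))
        x = rng.standard_normal((16, 16, 8)).astype(np.float32)
        assert aspp_forward(x, block).shape == (16, 16, 10)

    def test_pool_branch_of_constant_input_is_the_constant(self):
        x = Tensor(np.full((1, 3, 5, 5), 2.5, dtype=np.float32))
        pooled = expand_hw(global_avg_pool(x), 5, 5)
        np.testing.assert_allclose(pooled.data, 2.5)

    def test_separable_branches_have_fewer_parameters_than_full(self):
        aspp = ASPPBlock(16, 32, rng=np.random.default_rng(0))
        sep = aspp.atrous[0]
        sep_params = sep.depthwise.weight.data.size + sep.pointwise.weight.data.size
        full_params = Conv2d(16, 32, 3).weight.data.size
        assert sep_params < full_params


class TestReceptiveField:
    @pytest.mark.parametrize(
        "stack,expected",
        [((1, 2), 7), ((2, 3), 11), ((1,), 3), ((), 1), ((1, 2, 3), 13)],
    )
    def test_analytic_values(self, stack, expected):
        assert receptive_field(stack) == expected

    def test_agrees_with_impulse_response_oracle(self):
        """All dilation stacks of length <= 3 with rates <= 4, on 33x33."""
        from itertools import product

        stacks = [()]
        for n in (1, 2, 3):
            stacks.extend(product(range(1, 5), repeat=n))
        for stack in stacks:
            analytic = receptive_field(stack)
            if analytic <= 33:
                assert receptive_field_empirical(stack, grid=33) == analytic, stack

    def test_rejects_bad_dilation(self):
        with pytest.raises(ValueError):
            receptive_field((0, 2))
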