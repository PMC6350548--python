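"""Architecture spec construction, layer accounting and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mammodense as md
from mammodense.arch import (
    ArchConfig,
    BlockSpec,
    NetworkSpec,
    build_aspp,
    build_dense_block,
    build_transition_down,
    build_transition_up,
    conv_layers,
    validate,
)


class TestEffectiveKernel:
    @pytest.mark.parametrize("k,r,expected", [
        (3, 2, 5),   # 3x3 at rate 2 covers a 5x5 field
        (3, 3, 7),   # and a 7x7 field at rate 3
        (3, 1, 3),   # rate 1 is standard convolution
        (3, 6, 13),
        (1, 5, 1),
        (5, 2, 9),
    ])
    def test_formula(self, k, r, expected):
        assert md.effective_kernel_size(k, r) == expected

    @pytest.mark.parametrize("k,r", [(2, 1), (0, 1), (-3, 2), (3, 0)])
    def test_invalid_inputs_rejected(self, k, r):
        with pytest.raises(ValueError):
            md.effective_kernel_size(k, r)

    @given(k=st.sampled_from([1, 3, 5]), r=st.integers(1, 6))
    @settings(max_examples=50, derandomize=True)
    def test_formula_matches_zero_inserted_support(self, k, r):
        kernel = np.arange(1, k * k + 1, dtype=float).reshape(k, k)
        dilated = md.dilate_kernel(kernel, r)
        assert dilated.shape[0] == md.effective_kernel_size(k, r)


class TestDilateKernel:
    def test_rate_one_identity(self, rng):
        k = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(md.dilate_kernel(k, 1), k)

    def test_one_by_one_unchanged(self):
        np.testing.assert_array_equal(
            md.dilate_kernel(np.array([[2.0]]), 4), [[2.0]])

    def test_zero_insertion_structure(self):
        out = md.dilate_kernel(np.ones((3, 3)), 2)
        assert out.shape == (5, 5)
        assert np.count_nonzero(out) == 9
        assert np.count_nonzero(out == 0) == 16
        # originals sit at multiples of the rate
        np.testing.assert_array_equal(out[::2, ::2], np.ones((3, 3)))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            md.dilate_kernel(np.ones((2, 3)), 2)


class TestBlocks:
    def test_dense_block_channel_arithmetic(self):
        b = build_dense_block(48, 4, 12)
        convs = conv_layers(b)
        assert len(convs) == 4
        assert convs[2].in_channels == 48 + 2 * 12  # layer 3 sees 72
        assert b.attrs["out_channels"] == 48  # new features only

    def test_dense_block_single_layer(self):
        b = build_dense_block(10, 1, 7)
        assert b.attrs["out_channels"] == 7

    def test_transition_down_counts_one_unit(self):
        b = build_transition_down(100)
        assert b.attrs["out_channels"] == 100
        assert len(conv_layers(b)) == 2  # 1x1 conserve + stride-2 3x3
        spec = NetworkSpec(blocks=[b], skip_edges=[], config=md.tiny_config())
        assert md.count_layers(spec) == 1  # counted as one layer unit

    def test_transition_up_single_layer(self):
        b = build_transition_up(48, 48)
        convs = conv_layers(b)
        assert len(convs) == 1 and convs[0].kind == "transposed_conv"

    def test_aspp_layer_and_channel_accounting(self):
        b = build_aspp(240, 48, [6, 12, 18])
        assert len(conv_layers(b)) == 5  # 1x1 + three atrous + fusion
        concat_l = next(l for l in b.layers if l.kind == "concat")
        assert concat_l.in_channels == 240 + 4 * 48

    def test_aspp_rate_too_large_warns(self):
        with pytest.warns(UserWarning, match="effective kernel"):
            build_aspp(8, 4, [16], feature_side=8)

    def test_aspp_rates_must_increase(self):
        with pytest.raises(ValueError):
            build_aspp(8, 4, [4, 2])


class TestAssembly:
    def test_proposed_counts_47(self):
        spec = md.assemble_network(md.aspp_fc_densenet_config())
        assert md.count_layers(spec) == 47

    def test_baseline_counts_56(self):
        spec = md.assemble_network(md.fc_densenet56_config())
        assert md.count_layers(spec) == 56

    def test_count_difference_is_minus_nine(self):
        p = md.assemble_network(md.aspp_fc_densenet_config())
        b = md.assemble_network(md.fc_densenet56_config())
        assert md.count_layers(p) - md.count_layers(b) == -9

    def test_empty_spec_counts_zero(self):
        spec = NetworkSpec(blocks=[], skip_edges=[], config=md.tiny_config())
        assert md.count_layers(spec) == 0

    @pytest.mark.parametrize("cfg,expected", [
        (md.fc_densenet56_config(), 32),   # 5 transitions
        (md.aspp_fc_densenet_config(), 16),  # reduced to 4
        (md.tiny_config(), 4),
    ])
    def test_downsample_factor(self, cfg, expected):
        assert md.downsample_factor(md.assemble_network(cfg)) == expected

    def test_resolution_symmetric_and_preserved(self):
        spec = md.assemble_network(md.aspp_fc_densenet_config())
        assert spec.blocks[0].attrs["in_side"] == 512
        assert spec.blocks[-1].attrs["out_side"] == 512
        down_in = [b.attrs["in_side"] for b in spec.blocks
                   if b.name == "transition_down"]
        up_out = [b.attrs["out_side"] for b in spec.blocks
                  if b.name == "transition_up"]
        assert down_in == list(reversed(up_out))
        down_out = [b.attrs["out_side"] for b in spec.blocks
                    if b.name == "transition_down"]
        up_in = [b.attrs["in_side"] for b in spec.blocks
                 if b.name == "transition_up"]
        assert down_out == list(reversed(up_in))

    def test_skip_edges_connect_equal_resolutions(self):
        spec = md.assemble_network(md.aspp_fc_densenet_config())
        assert len(spec.skip_edges) == 4
        for src, dst in spec.skip_edges:
            assert (spec.blocks[src].attrs["in_side"]
                    == spec.blocks[dst].attrs["out_side"])
            assert spec.blocks[src].skip_output

    def test_channel_bookkeeping_walk(self):
        """Every dense layer's declared input equals the concatenation
        arithmetic of the block input and previous layer outputs."""
        for cfg in (md.aspp_fc_densenet_config(), md.fc_densenet56_config(),
                    md.tiny_config()):
            spec = md.assemble_network(cfg)
            validate(spec)  # raises on any inconsistency
            for b in spec.blocks:
                if b.name == "dense_block":
                    for i, l in enumerate(conv_layers(b)):
                        assert l.in_channels == (b.attrs["in_channels"]
                                                 + i * b.attrs["growth"])

    def test_indivisible_input_side_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchConfig(input_side=500)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(growth_rate=0)
        with pytest.raises(ValueError):
            ArchConfig(aspp_rates=(6, 6, 18))


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_round_trip(self, fmt):
        spec = md.assemble_network(md.tiny_config())
        text = spec.to_yaml() if fmt == "yaml" else spec.to_json()
        back = (NetworkSpec.from_yaml(text) if fmt == "yaml"
                else NetworkSpec.from_json(text))
        assert back.to_dict() == spec.to_dict()
        assert md.count_layers(back) == md.count_layers(spec)
        validate(back)
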