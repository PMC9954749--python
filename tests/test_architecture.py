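import numpy as np
import pytest

from fabnet import nn
from fabnet.architecture import (
    ArchitectureError,
    ArchitectureSpec,
    ConvBlockSpec,
    FabNetModel,
    FeatureShape,
    build_model,
    count_conv_layers,
    count_trainable_parameters,
    default_fabnet_spec,
    infer_feature_shapes,
    parameter_count_formula,
    tiny_fabnet_spec,
)


class TestDefaultSpec:
    def test_canonical_topology(self):
        spec = default_fabnet_spec(head_classes=2)
        assert len(spec.blocks) == 10
        assert len(spec.pairs) == 5
        assert len(spec.stage_taps) == 5
        assert spec.pairs == ((1, 2), (3, 4), (5, 6), (7, 8), (9, 10))

    def test_filter_progression(self):
        spec = default_fabnet_spec(head_classes=2)
        filters = tuple(b.filters_parallel for b in spec.blocks)
        assert filters == (16, 32, 32, 64, 64, 128, 128, 256, 256, 512)
        # stated counts: B8 = 256, B10 = 512
        assert spec.blocks[7].filters_parallel == 256
        assert spec.blocks[9].filters_parallel == 512

    def test_head_independence(self):
        """Binary and 9-class specs differ only in the dense head width."""
        s2 = default_fabnet_spec(head_classes=2)
        s9 = default_fabnet_spec(head_classes=9)
        assert s2.blocks == s9.blocks
        assert s2.pairs == s9.pairs
        assert s2.head_classes == 2 and s9.head_classes == 9

    def test_invalid_head_rejected(self):
        with pytest.raises(ArchitectureError):
            default_fabnet_spec(head_classes=1)

    def test_reduce_width_rule(self):
        spec = default_fabnet_spec()
        for b in spec.blocks:
            assert b.reduce_width == min(b.filters_parallel, 32)

    def test_serialization_round_trip(self, tmp_path):
        spec = default_fabnet_spec(head_classes=9)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert ArchitectureSpec.from_json(path) == spec


class TestSpecInvariants:
    def test_reduce_width_cannot_exceed_concat(self):
        with pytest.raises(ArchitectureError):
            ConvBlockSpec(index=1, filters_parallel=4, reduce_width=9)

    def test_pairs_must_cover_blocks(self):
        blocks = tuple(ConvBlockSpec(index=i, filters_parallel=16, reduce_width=16) for i in (1, 2))
        with pytest.raises(ArchitectureError):
            ArchitectureSpec(blocks=blocks, pairs=((1, 1),), stage_taps=("C1",))

    def test_tap_count_must_match_pairs(self):
        blocks = tuple(ConvBlockSpec(index=i, filters_parallel=16, reduce_width=16) for i in (1, 2))
        with pytest.raises(ArchitectureError):
            ArchitectureSpec(blocks=blocks, pairs=((1, 2),), stage_taps=("C1", "C2"))


class TestLayerCount:
    def test_default_spec_has_thirty_conv_layers(self):
        assert count_conv_layers(default_fabnet_spec()) == 30

    @pytest.mark.parametrize("n_blocks", [2, 4, 6])
    def test_three_convs_per_block(self, n_blocks):
        spec = tiny_fabnet_spec(filters=(16,) * n_blocks)
        assert count_conv_layers(spec) == 3 * n_blocks
        # each compiled block holds exactly one 5x5, one 3x3 and one 1x1 conv
        model = build_model(spec, seed=0)
        for blk in model.blocks:
            kernels = sorted(l.kernel for l in blk.layers if isinstance(l, nn.Conv2D))
            assert kernels == [1, 3, 5]

    def test_built_model_agrees(self):
        spec = default_fabnet_spec()
        model = build_model(spec, seed=0)
        assert len(model.conv_layers) == count_conv_layers(spec) == 30


class TestParameterCount:
    def test_smallest_conv(self):
        conv = nn.Conv2D(1, 1, 1, np.random.default_rng(0))
        assert conv.n_params() == 2

    def test_block_b1_hand_sum(self):
        """B1 (3 input ch, 16 filters, reduce 16, BN): 1216+448+528+32."""
        spec = default_fabnet_spec()
        one_block = tiny_fabnet_spec(filters=(16, 16), reduce_cap=16)
        model = build_model(one_block, seed=0)
        b1 = model.blocks[0]
        assert b1.conv5.n_params() == 5 * 5 * 3 * 16 + 16 == 1216
        assert b1.conv3.n_params() == 3 * 3 * 3 * 16 + 16 == 448
        assert b1.conv1.n_params() == 32 * 16 + 16 == 528
        assert b1.bn.n_params() == 32
        assert sum(l.n_params() for l in b1.layers) == 2224

    def test_full_default_binary_model(self):
        spec = default_fabnet_spec(head_classes=2)
        model = build_model(spec, seed=0)
        assert count_trainable_parameters(model) == 2_189_810
        assert count_trainable_parameters(model) <= 3_239_000

    @pytest.mark.parametrize("head_classes", [2, 8, 9])
    @pytest.mark.parametrize("reduce_cap", [16, 32, 64])
    def test_formula_matches_built_model_exactly(self, head_classes, reduce_cap):
        """Closed-form summation over the spec equals the compiled model."""
        spec = default_fabnet_spec(head_classes=head_classes, reduce_cap=reduce_cap)
        model = build_model(spec, seed=0)
        assert parameter_count_formula(spec) == count_trainable_parameters(model)

    def test_formula_matches_tiny_variants(self):
        for filters in [(4, 8), (8, 16, 16, 32)]:
            spec = tiny_fabnet_spec(filters=filters, reduce_cap=8)
            model = build_model(spec, seed=0)
            assert parameter_count_formula(spec) == count_trainable_parameters(model)


class TestShapeInference:
    def test_default_trace(self):
        spec = default_fabnet_spec()
        shapes = infer_feature_shapes(spec)
        assert shapes["pool1"] == FeatureShape(112, 112, 48)
        assert shapes["pool5"] == FeatureShape(7, 7, 64)
        assert shapes["stage_fusion"] == FeatureShape(7, 7, 304)
        assert shapes["gap"].channels == 304
        assert shapes["head"].channels == 2

    def test_blocks_preserve_spatial_dims(self):
        spec = default_fabnet_spec()
        shapes = infer_feature_shapes(spec)
        h, w = 224, 224
        for p, (a, b) in enumerate(spec.pairs):
            assert (shapes[f"B{a}"].height, shapes[f"B{a}"].width) == (h, w)
            assert (shapes[f"B{b}"].height, shapes[f"B{b}"].width) == (h, w)
            h, w = h // 2, w // 2

    def test_non_divisible_input_rejected(self):
        spec = default_fabnet_spec()
        with pytest.raises(ArchitectureError):
            infer_feature_shapes(spec, FeatureShape(100, 100, 3))

    def test_probed_tensor_shapes_agree_with_trace(self):
        """Running real tensors through the model matches the shape trace."""
        spec = tiny_fabnet_spec(filters=(4, 8, 8, 8), reduce_cap=4, input_size=16)
        shapes = infer_feature_shapes(spec)
        model = build_model(spec, seed=0)
        x = np.random.default_rng(0).random((2, 3, 16, 16))
        taps = []
        cur = x
        for p in range(spec.n_pairs):
            a_out = model.blocks[2 * p].forward(cur)
            b_out = model.blocks[2 * p + 1].forward(a_out)
            a, b = spec.pairs[p]
            assert a_out.shape[1:] == (
                shapes[f"B{a}"].channels, shapes[f"B{a}"].height, shapes[f"B{a}"].width
            )
            assert b_out.shape[1:] == (
                shapes[f"B{b}"].channels, shapes[f"B{b}"].height, shapes[f"B{b}"].width
            )
            fused = np.concatenate([a_out, b_out], axis=1)
            pooled = model.pool.forward(fused)
            sh = shapes[f"pool{p + 1}"]
            assert pooled.shape[1:] == (sh.channels, sh.height, sh.width)
            taps.append(pooled)
            cur = pooled


class TestBuiltModel:
    def test_single_block_padding_preserves_size(self):
        """Stride-1 zero-padded convs keep an 8x8 input at 8x8."""
        rng = np.random.default_rng(0)
        conv5 = nn.Conv2D(3, 4, 5, rng)
        conv3 = nn.Conv2D(3, 4, 3, rng)
        x = rng.random((1, 3, 8, 8))
        assert conv5.forward(x).shape == (1, 4, 8, 8)
        assert conv3.forward(x).shape == (1, 4, 8, 8)

    def test_softmax_rows_sum_to_one(self):
        spec = tiny_fabnet_spec(filters=(4, 8), reduce_cap=4, input_size=16)
        model = build_model(spec, seed=0)
        x = np.random.default_rng(1).random((5, 3, 16, 16))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_default_model_forward_shape(self):
        """The full 10-block model maps a 64x64 input to binary logits."""
        spec = default_fabnet_spec()
        model = build_model(spec, seed=0)
        x = np.random.default_rng(0).random((1, 3, 64, 64))
        assert model.forward(x).shape == (1, 2)

    def test_build_determinism(self):
        spec = tiny_fabnet_spec(filters=(4, 8), reduce_cap=4)
        m1 = build_model(spec, seed=123)
        m2 = build_model(spec, seed=123)
        for (n1, a1), (n2, a2) in zip(m1.state_arrays(), m2.state_arrays()):
            assert n1 == n2
            np.testing.assert_array_equal(a1, a2)

    def test_different_seeds_differ(self):
        spec = tiny_fabnet_spec(filters=(4, 8), reduce_cap=4)
        m1 = build_model(spec, seed=1)
        m2 = build_model(spec, seed=2)
        assert not np.array_equal(m1.head.params["w"], m2.head.params["w"])

    def test_checkpoint_round_trip(self, tmp_path):
        spec = tiny_fabnet_spec(filters=(4, 8), reduce_cap=4, input_size=16)
        m1 = build_model(spec, seed=5)
        path = tmp_path / "model.npz"
        m1.save(path)
        m2 = build_model(spec, seed=99)
        m2.load(path)
        x = np.random.default_rng(0).random((2, 3, 16, 16))
        np.testing.assert_array_equal(m1.forward(x), m2.forward(x))
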