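"""Architecture contracts: parameter accounting, shapes, identities."""

import itertools

import numpy as np
import pytest

from nodulenet import models
from nodulenet.nn import core

BASELINE_2 = 23_512_130
FULL_HYBRID = 56_973_890
MST_TOTAL = 33_461_760
STAGE_CHANNELS = (256, 512, 1024, 2048)


class TestParameterAccounting:
    def test_baseline_two_class_count(self):
        model = models.build_baseline(num_classes=2)
        assert models.count_parameters(model) == BASELINE_2

    def test_baseline_thousand_class_count(self):
        # canonical 50-layer network head arithmetic:
        # 23,512,130 - (2048*2+2) + (2048*1000+1000)
        model = models.build_baseline(num_classes=1000)
        assert models.count_parameters(model) == BASELINE_2 - (2048 * 2 + 2) + (2048 * 1000 + 1000)

    @pytest.mark.parametrize(
        "channels,expected",
        [(256, 395_776), (2048, 25_186_304)],
    )
    def test_mst_block_closed_form(self, channels, expected):
        assert models.mst_block_parameter_count(channels) == expected
        # cross-check the closed form by enumerating a constructed block
        block = models.MSTBlock(channels)
        assert sum(p.data.size for p in block.parameters()) == expected

    def test_mst_block_sum_matches_model_difference(self):
        assert sum(models.mst_block_parameter_count(c) for c in STAGE_CHANNELS) == MST_TOTAL
        assert MST_TOTAL == FULL_HYBRID - BASELINE_2

    def test_full_hybrid_count(self):
        model = models.MSTResNet(models.BackboneConfig())
        assert models.count_parameters(model) == FULL_HYBRID

    def test_parameter_ledger_all_stage_subsets(self):
        """count_parameters equals baseline + sum(6C^2+10C) for all 16 subsets."""
        for r in range(5):
            for subset in itertools.combinations((1, 2, 3, 4), r):
                cfg = models.BackboneConfig(mst_stages=frozenset(subset))
                model = models.MSTResNet(cfg)
                expected = BASELINE_2 + sum(
                    models.mst_block_parameter_count(STAGE_CHANNELS[s - 1]) for s in subset
                )
                assert models.count_parameters(model) == expected
                assert models.expected_parameter_count(cfg) == expected

    def test_spatial_attention_is_parameter_free(self):
        empty = models.MSTResNet(models.BackboneConfig(mst_stages=frozenset()))
        assert models.count_parameters(empty) == BASELINE_2


class TestConfigValidation:
    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            models.BackboneConfig(mst_stages=frozenset({0, 5}))

    def test_head_split_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            models.MSTBlock(256, models.MSTBlockConfig(num_heads=3))

    def test_nonpositive_grid_rejected(self):
        with pytest.raises(ValueError, match="attn_grid"):
            models.MSTBlockConfig(attn_grid=0).validate(256)

    def test_pretrained_unavailable_is_explicit(self):
        with pytest.raises(RuntimeError, match="pretrained=False"):
            models.build_baseline(2, pretrained=True)


class TestMSTBlockForward:
    def test_shape_preserved_and_pooling_condition(self, rng):
        # stage-1 geometry pools 56 -> 14 (196 tokens); stage-4 (7x7) does not
        block1 = models.MSTBlock(8)
        x1 = core.Tensor(rng.standard_normal((1, 8, 56, 56)).astype(np.float32))
        block1.eval()
        y1 = block1(x1)
        assert y1.shape == x1.shape
        assert block1.last_pooled and block1.last_token_count == 196

        block4 = models.MSTBlock(8)
        block4.eval()
        x4 = core.Tensor(rng.standard_normal((2, 8, 7, 7)).astype(np.float32))
        y4 = block4(x4)
        assert y4.shape == x4.shape
        assert not block4.last_pooled and block4.last_token_count == 49

    def test_zeroed_projections_give_exact_identity(self, rng):
        block = models.MSTBlock(16)
        block.zero_projections()
        block.eval()
        x = core.Tensor(rng.standard_normal((2, 16, 20, 20)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_finite_outputs(self, rng):
        block = models.MSTBlock(16)
        models._init_mst_block(block, rng)
        block.eval()
        x = core.Tensor(rng.standard_normal((2, 16, 28, 28)).astype(np.float32) * 10)
        assert np.isfinite(block(x).data).all()


class TestSpatialAttention:
    def test_zero_features_flagged_degenerate(self):
        res = models.spatial_attention(np.zeros((1, 4, 7, 7), np.float32), out_size=(28, 28))
        assert res.degenerate.all()
        np.testing.assert_array_equal(res.attention_map, 0.0)
        np.testing.assert_array_equal(res.gated.data, 0.0)  # gate 0.5 times zero features

    def test_point_source_peaks_at_upsampled_location(self):
        f = np.zeros((1, 4, 7, 7), np.float32)
        f[0, :, 2, 5] = 50.0
        res = models.spatial_attention(f, out_size=(224, 224))
        r, c = np.unravel_index(res.attention_map[0].argmax(), (224, 224))
        # cell (2,5) of a 7-grid maps to the 32-px block starting at (64,160)
        assert 64 <= r < 96 and 160 <= c < 192

    def test_maps_bounded_for_random_inputs(self, rng):
        for _ in range(20):
            f = rng.standard_normal((2, 8, 7, 7)).astype(np.float32) * rng.uniform(0.1, 30)
            res = models.spatial_attention(f, out_size=(56, 56))
            assert res.attention_map.min() >= 0.0 and res.attention_map.max() <= 1.0


class TestEndToEnd:
    def test_stage_shapes_for_224_input(self, rng):
        model = models.build_mst_resnet(seed=0)
        model.eval()
        x = core.Tensor(rng.standard_normal((1, 3, 224, 224)).astype(np.float32))
        with core.no_grad():
            h = model.backbone.stem(x)
            for s, (c, side) in models.STAGE_SHAPES.items():
                h = model.backbone.stage(s)(h)
                assert h.shape == (1, c, side, side)
                assert np.isfinite(h.data).all()
                h = model.mst[str(s)](h)
                assert h.shape == (1, c, side, side)
                assert np.isfinite(h.data).all()

    def test_forward_contract_and_determinism(self, rng):
        model = models.build_mst_resnet(seed=7)
        model.eval()
        x = rng.standard_normal((2, 3, 224, 224)).astype(np.float32)
        with core.no_grad():
            out1 = model(x)
            out2 = model(x)
        assert out1.logits.shape == (2, 2)
        assert out1.attention_map.shape == (2, 224, 224)
        np.testing.assert_allclose(out1.probabilities.sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_array_equal(out1.logits.data, out2.logits.data)
        np.testing.assert_array_equal(out1.attention_map, out2.attention_map)

    def test_zero_weight_mst_matches_gated_baseline_bitwise(self, rng):
        """Zeroing every MST projection reproduces the attention-gated
        baseline exactly (same backbone seed)."""
        full = models.build_mst_resnet(models.BackboneConfig(), seed=3)
        full.zero_mst_projections()
        full.eval()
        empty = models.build_mst_resnet(models.BackboneConfig(mst_stages=frozenset()), seed=3)
        empty.eval()
        x = rng.standard_normal((2, 3, 224, 224)).astype(np.float32)
        with core.no_grad():
            a, b = full(x), empty(x)
        np.testing.assert_array_equal(a.logits.data, b.logits.data)
        np.testing.assert_array_equal(a.attention_map, b.attention_map)


class TestCheckpoints:
    def test_round_trip_and_config_guard(self, tmp_path, rng):
        cfg = models.BackboneConfig(mst_stages=frozenset({4}))
        model = models.build_mst_resnet(cfg, seed=5)
        model.eval()
        path = tmp_path / "model.npz"
        models.save_checkpoint(model, path)
        loaded = models.load_checkpoint(path, expected_config=cfg)
        x = rng.standard_normal((1, 3, 64, 64)).astype(np.float32)
        with core.no_grad():
            np.testing.assert_array_equal(model(x).logits.data, loaded(x).logits.data)
        other = models.BackboneConfig(mst_stages=frozenset({1, 2}))
        with pytest.raises(ValueError, match="config"):
            models.load_checkpoint(path, expected_config=other)
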