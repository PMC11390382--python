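"""Backbone hierarchy: tokenizer, blocks, downsamplers, shape laws."""

import numpy as np
import pytest

from natmil._tensor import Tensor
from natmil._nn import LayerNorm, Mlp
from natmil.backbone import (ConvTokenizer, DenseAttention, Downsampler,
                             NatBackbone, NatBlock, NatConfig, _GridCtx,
                             downsample, forward_backbone, nat_block, tokenize)
from natmil.na import (GridFeatureMap, build_neighborhood_index,
                       oracle_masked_attention)


def tiny_cfg(**kw):
    base = dict(depths=(1, 1, 1, 1), heads=2, mlp_ratio=2.0, k=4,
                base_channels=8, layer_scale_init=0.1, mode="image", seed=0)
    base.update(kw)
    return NatConfig(**base)


class TestTokenizer:
    def test_quarter_resolution(self):
        rng = np.random.default_rng(0)
        tok = ConvTokenizer(3, 8, rng)
        out = tokenize(np.zeros((224, 224, 3)), tok)
        assert out.X.shape == (56, 56, 8)

    def test_8_to_2(self):
        tok = ConvTokenizer(3, 4, np.random.default_rng(0))
        assert tokenize(np.zeros((8, 8, 3)), tok).X.shape == (2, 2, 4)

    def test_zero_input_zero_bias_zero_output(self):
        tok = ConvTokenizer(3, 4, np.random.default_rng(0))
        tok.conv1.bias.data[:] = 0
        tok.conv2.bias.data[:] = 0
        out = tokenize(np.zeros((16, 16, 3)), tok)
        assert np.allclose(out.X, 0.0)


class TestDownsample:
    @pytest.mark.parametrize("h,w,expect", [(56, 56, (28, 28)), (2, 2, (1, 1)),
                                            (7, 7, (4, 4))])
    def test_spatial(self, h, w, expect):
        ds = Downsampler(4, np.random.default_rng(0))
        out = downsample(GridFeatureMap(np.random.default_rng(1).normal(size=(h, w, 4))), ds)
        assert out.X.shape == (*expect, 8)

    def test_mask_or_pooling(self):
        valid = np.zeros((4, 4), dtype=bool)
        valid[3, 3] = True
        ds = Downsampler(2, np.random.default_rng(0))
        out = downsample(GridFeatureMap(np.zeros((4, 4, 2)), valid), ds)
        assert out.valid.tolist() == [[False, False], [False, True]]


class TestBlock:
    def test_layerscale_zero_identity(self):
        blk = NatBlock(8, 2, 4, 2.0, 0.0, np.random.default_rng(0))
        X = GridFeatureMap(np.random.default_rng(1).normal(size=(5, 5, 8)))
        out = nat_block(X, blk)
        assert np.allclose(out.X, X.X, atol=1e-12)

    def test_masked_positions_stay_zero(self):
        valid = np.ones((4, 4), dtype=bool)
        valid[1, 2] = False
        blk = NatBlock(8, 2, 4, 2.0, 0.1, np.random.default_rng(0))
        arr = np.random.default_rng(2).normal(size=(4, 4, 8)) * valid[:, :, None]
        out = nat_block(GridFeatureMap(arr, valid), blk)
        assert np.all(out.X[1, 2] == 0)

    def test_matches_reference_composition(self):
        # straight-line recomposition: LN -> NA oracle -> gamma1 residual,
        # LN -> MLP -> gamma2 residual, computed with numpy only
        rng = np.random.default_rng(3)
        blk = NatBlock(8, 2, 9, 2.0, 0.1, rng)
        blk.attn.bias_table.data[:] = rng.normal(size=blk.attn.bias_table.shape) * 0.2
        X = GridFeatureMap(rng.normal(size=(6, 6, 8)))
        got = nat_block(X, blk)

        def ln(x, mod):
            mu = x.mean(-1, keepdims=True)
            var = ((x - mu) ** 2).mean(-1, keepdims=True)
            return (x - mu) / np.sqrt(var + mod.eps) * mod.gamma.data + mod.beta.data

        idx = build_neighborhood_index(6, 6, 9)
        y = oracle_masked_attention(GridFeatureMap(ln(X.X, blk.norm1)), blk.attn, idx).X
        x1 = X.X + blk.gamma1.data * y
        h = ln(x1, blk.norm2)
        flat = h.reshape(36, 8)
        z = Tensor(flat)
        mlp = blk.mlp(z).data.reshape(6, 6, 8)
        expect = x1 + blk.gamma2.data * mlp
        assert np.abs(got.X - expect).max() < 1e-5


class TestBackbone:
    def test_image_mode_stage_sizes(self):
        out, pooled = forward_backbone(np.random.default_rng(0).normal(size=(64, 64, 3)),
                                       NatBackbone(tiny_cfg()))
        shapes = [g.X.shape for g in out.maps]
        assert shapes == [(16, 16, 8), (8, 8, 16), (4, 4, 32), (2, 2, 64)]
        assert pooled.shape == (64,)

    def test_tile_mode_stage_sizes(self):
        cfg = tiny_cfg(mode="tiles", in_channels=12)
        gm = GridFeatureMap(np.random.default_rng(1).normal(size=(24, 24, 12)))
        out, pooled = forward_backbone(gm, NatBackbone(cfg))
        assert [g.X.shape for g in out.maps] == [
            (24, 24, 8), (12, 12, 16), (6, 6, 32), (3, 3, 64)]

    @pytest.mark.parametrize("size", [32, 96])
    def test_halve_double_law(self, size):
        out, _ = forward_backbone(np.zeros((size, size, 3)),
                                  NatBackbone(tiny_cfg()))
        h, c = size // 4, 8
        for g in out.maps:
            assert g.X.shape == (h, h, c)
            h, c = (h + 1) // 2, c * 2

    def test_param_count_input_invariant(self):
        m = NatBackbone(tiny_cfg())
        n0 = sum(p.data.size for p in m.parameters())
        forward_backbone(np.zeros((32, 32, 3)), m)
        forward_backbone(np.zeros((64, 64, 3)), m)
        assert sum(p.data.size for p in m.parameters()) == n0

    def test_empty_depths_is_tokenize_downsample_only(self):
        cfg = tiny_cfg(depths=(0, 0, 0, 0))
        out, _ = forward_backbone(np.random.default_rng(0).normal(size=(32, 32, 3)),
                                  NatBackbone(cfg))
        assert [g.X.shape for g in out.maps] == [
            (8, 8, 8), (4, 4, 16), (2, 2, 32), (1, 1, 64)]

    def test_deterministic(self):
        x = np.random.default_rng(5).normal(size=(32, 32, 3))
        a = forward_backbone(x, NatBackbone(tiny_cfg()))[1]
        b = forward_backbone(x, NatBackbone(tiny_cfg()))[1]
        assert np.array_equal(a, b)

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError):
            forward_backbone(np.zeros((2, 2, 3)), NatBackbone(tiny_cfg()))

    def test_full_k_equals_global_mixer(self):
        # NA with maximal k vs DenseAttention with copied projections
        rng = np.random.default_rng(7)
        na_blk = NatBlock(8, 2, 64, 2.0, 0.1, np.random.default_rng(7))
        gl_blk = NatBlock(8, 2, 64, 2.0, 0.1, np.random.default_rng(7),
                          mixer="global")
        for name in ("Wq", "Wk", "Wv", "Wo", "bq", "bk", "bv", "bo"):
            getattr(gl_blk.attn, name).data = getattr(na_blk.attn, name).data.copy()
        for mod_g, mod_n in ((gl_blk.norm1, na_blk.norm1), (gl_blk.norm2, na_blk.norm2)):
            mod_g.gamma.data = mod_n.gamma.data.copy()
            mod_g.beta.data = mod_n.beta.data.copy()
        gl_blk.mlp.fc1.weight.data = na_blk.mlp.fc1.weight.data.copy()
        gl_blk.mlp.fc1.bias.data = na_blk.mlp.fc1.bias.data.copy()
        gl_blk.mlp.fc2.weight.data = na_blk.mlp.fc2.weight.data.copy()
        gl_blk.mlp.fc2.bias.data = na_blk.mlp.fc2.bias.data.copy()
        gl_blk.gamma1.data = na_blk.gamma1.data.copy()
        gl_blk.gamma2.data = na_blk.gamma2.data.copy()
        X = GridFeatureMap(rng.normal(size=(8, 8, 8)))
        out_na = nat_block(X, na_blk)
        out_gl = nat_block(X, gl_blk)
        assert np.abs(out_na.X - out_gl.X).max() < 1e-4

    def test_conv_mixer_runs(self):
        blk = NatBlock(8, 2, 4, 2.0, 0.1, np.random.default_rng(0), mixer="conv")
        X = GridFeatureMap(np.random.default_rng(1).normal(size=(5, 5, 8)))
        out = nat_block(X, blk)
        assert out.X.shape == (5, 5, 8)

    def test_window_mixer_blocks_isolated(self):
        # tokens in different windows cannot influence one another
        blk = NatBlock(4, 2, 4, 2.0, 0.1, np.random.default_rng(0), mixer="window")
        base = np.random.default_rng(2).normal(size=(4, 4, 4))
        mod = base.copy()
        mod[3, 3] += 10.0  # bottom-right window
        out_a = nat_block(GridFeatureMap(base), blk)
        out_b = nat_block(GridFeatureMap(mod), blk)
        assert np.allclose(out_a.X[:2, :2], out_b.X[:2, :2], atol=1e-10)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            NatConfig(depths=(1, 1, 1))
        with pytest.raises(ValueError):
            NatConfig(heads=3, base_channels=8)
        with pytest.raises(ValueError):
            NatConfig(mixer="bogus")
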