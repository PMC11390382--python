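"""Hierarchical neighborhood-attention transformer backbone.

Layout: an overlapping-convolution tokenizer (two 3×3 stride-2 convs)
or, for tile-feature grids, a 1×1 linear embedding; four stages of
pre-norm transformer blocks whose token mixer is neighborhood attention
(swappable for blocked-window attention, global attention, or a
depthwise convolution in ablations); and 3×3 stride-2 convolutional
downsamplers between stages that halve space and double channels.
Residual branches are scaled by learnable per-channel LayerScale
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Conv2d, LayerNorm, Linear, Mlp, Module, trunc_normal
from ._tensor import Tensor, concat
from .na import (GridFeatureMap, NeighborhoodAttention, build_neighborhood_index,
                 table_radius)

__all__ = [
    "NatConfig", "StageOutput", "NatBackbone", "NatBlock", "ConvTokenizer",
    "Downsampler", "NatContextualizer", "DenseAttention",
    "tokenize", "nat_block", "downsample", "forward_backbone",
    "MIXERS",
]

MIXERS = ("neighborhood", "window", "global", "conv")


@dataclass
class NatConfig:
    """Reference configuration: depths 3,4,18,5 / 2 heads / MLP ratio 3."""

    depths: tuple = (3, 4, 18, 5)
    heads: int = 2
    mlp_ratio: float = 3.0
    k: int = 9
    base_channels: int = 64
    layer_scale_init: float = 1e-5
    drop_path: float = 0.0
    mode: str = "tiles"            # "tiles" | "image"
    tokenizer: str = "auto"        # "conv" | "linear" | "auto" (by mode)
    mixer: str = "neighborhood"
    in_channels: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.depths) != 4:
            raise ValueError("depths must list exactly 4 stage depths")
        for i in range(4):
            if (self.base_channels * 2 ** i) % self.heads:
                raise ValueError("heads must divide every stage's channel count")
        if self.mixer not in MIXERS:
            raise ValueError(f"unknown mixer {self.mixer!r}; valid: {MIXERS}")

    @property
    def tokenizer_kind(self) -> str:
        if self.tokenizer != "auto":
            return self.tokenizer
        return "conv" if self.mode == "image" else "linear"


@dataclass
class StageOutput:
    maps: list  # four GridFeatureMaps at /1,/2,/4,/8 of tokenized resolution


class _GridCtx:
    """Gather/scatter bookkeeping between a masked grid and its flat
    valid-token representation, plus cached attention indices."""

    def __init__(self, h: int, w: int, valid: np.ndarray):
        self.h, self.w = h, w
        self.valid = np.asarray(valid, dtype=bool)
        pos = np.argwhere(self.valid)
        self.rows, self.cols = pos[:, 0], pos[:, 1]
        self.n = len(pos)
        if self.n == 0:
            raise ValueError("stage has no valid positions")
        gi = np.full((h, w), self.n, dtype=np.int64)
        gi[self.rows, self.cols] = np.arange(self.n)
        self.grid_idx = gi
        self._na_cache: dict = {}
        self._win_cache: dict = {}

    def na_index(self, k: int):
        if k not in self._na_cache:
            self._na_cache[k] = build_neighborhood_index(self.h, self.w, k, self.valid)
        return self._na_cache[k]

    def window_allow(self, k: int) -> np.ndarray:
        """Boolean (n, n) same-block matrix for blocked-window attention
        with window side ⌈√k⌉ (Swin-style non-overlapping partition)."""
        if k not in self._win_cache:
            m = table_radius(k)
            bid = (self.rows // m) * ((self.w + m - 1) // m) + self.cols // m
            self._win_cache[k] = bid[:, None] == bid[None, :]
        return self._win_cache[k]

    def to_grid(self, x_flat: Tensor) -> Tensor:
        b, n, c = x_flat.shape
        padded = concat([x_flat, Tensor(np.zeros((b, 1, c)))], axis=1)
        return padded[(slice(None), self.grid_idx)]

    def to_flat(self, x_grid: Tensor) -> Tensor:
        return x_grid[(slice(None), self.rows, self.cols)]


class DenseAttention(Module):
    """Full multi-head attention, optionally restricted by an allow-mask.

    Used for the 'global' and 'window' ablation mixers; carries no
    positional bias, and therefore zero attention-specific spatial
    parameters beyond the projections.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.Wq = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wk = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wv = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wo = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.bq = Tensor(np.zeros(dim), requires_grad=True)
        self.bk = Tensor(np.zeros(dim), requires_grad=True)
        self.bv = Tensor(np.zeros(dim), requires_grad=True)
        self.bo = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor, allow: np.ndarray | None = None) -> Tensor:
        b, n, c = x.shape
        h, dh = self.heads, self.dh
        q = (x @ self.Wq + self.bq).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        kk = (x @ self.Wk + self.bk).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        v = (x @ self.Wv + self.bv).reshape(b, n, h, dh).transpose(0, 2, 1, 3)
        logits = q @ kk.transpose(0, 1, 3, 2) * float(1.0 / np.sqrt(dh))
        if allow is not None:
            logits = logits + np.where(allow, 0.0, -1e9)
        p = logits.softmax(axis=-1)
        out = (p @ v).transpose(0, 2, 1, 3).reshape(b, n, c)
        return out @ self.Wo + self.bo


class NatBlock(Module):
    """Pre-norm transformer encoder block: x + γ₁·mix(LN(x)), then
    x + γ₂·MLP(LN(x)), with LayerScale γ vectors."""

    def __init__(self, dim: int, heads: int, k: int, mlp_ratio: float,
                 layer_scale_init: float, rng: np.random.Generator,
                 mixer: str = "neighborhood"):
        if mixer not in MIXERS:
            raise ValueError(f"unknown mixer {mixer!r}; valid: {MIXERS}")
        self.mixer = mixer
        self.k = k
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, max(1, int(round(mlp_ratio * dim))), rng)
        self.gamma1 = Tensor(np.full(dim, layer_scale_init), requires_grad=True)
        self.gamma2 = Tensor(np.full(dim, layer_scale_init), requires_grad=True)
        if mixer == "neighborhood":
            self.attn = NeighborhoodAttention(dim, heads, k, rng)
        elif mixer in ("global", "window"):
            self.attn = DenseAttention(dim, heads, rng)
        else:  # conv
            self.attn = Conv2d(dim, dim, 3, 1, 1, rng, depthwise=True)

    def __call__(self, x_flat: Tensor, ctx: _GridCtx) -> Tensor:
        y = self.norm1(x_flat)
        if self.mixer == "neighborhood":
            y = self.attn(y, ctx.na_index(min(self.k, ctx.n)))
        elif self.mixer == "global":
            y = self.attn(y)
        elif self.mixer == "window":
            y = self.attn(y, allow=ctx.window_allow(self.k))
        else:
            y = ctx.to_flat(self.attn(ctx.to_grid(y)))
        x = x_flat + self.gamma1 * y
        return x + self.gamma2 * self.mlp(self.norm2(x))


class ConvTokenizer(Module):
    """Two consecutive 3×3 stride-2 overlapping convolutions: spatial
    size drops to ⌈·/4⌉, channels go to ``base_channels``."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, 2, 1, rng)
        self.conv2 = Conv2d(c_out, c_out, 3, 2, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).gelu())


class Downsampler(Module):
    """3×3 stride-2 convolution doubling channels, halving space (ceil)."""

    def __init__(self, c_in: int, rng: np.random.Generator):
        self.conv = Conv2d(c_in, 2 * c_in, 3, 2, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


def _pool_mask(valid: np.ndarray) -> np.ndarray:
    """Validity after one halving: logical OR over each 2×2 input block."""
    h, w = valid.shape
    oh, ow = (h + 1) // 2, (w + 1) // 2
    out = np.zeros((oh, ow), dtype=bool)
    for dr in (0, 1):
        for dc in (0, 1):
            sub = valid[dr::2, dc::2]
            out[:sub.shape[0], :sub.shape[1]] |= sub
    return out


class NatBackbone(Module):
    """Four-stage hierarchy; returns all stage maps plus a masked
    global-average-pooled final embedding."""

    def __init__(self, config: NatConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0 = config.base_channels
        if config.tokenizer_kind == "conv":
            self.tokenizer = ConvTokenizer(config.in_channels, c0, rng)
        else:
            self.tokenizer = Linear(config.in_channels, c0, rng)
        self.stages = []
        self.downsamplers = []
        for i, depth in enumerate(config.depths):
            dim = c0 * 2 ** i
            self.stages.append([
                NatBlock(dim, config.heads, config.k, config.mlp_ratio,
                         config.layer_scale_init, rng, mixer=config.mixer)
                for _ in range(depth)
            ])
            if i < 3:
                self.downsamplers.append(Downsampler(dim, rng))
        self.norm = LayerNorm(c0 * 8)

    @property
    def out_dim(self) -> int:
        return self.config.base_channels * 8

    def forward(self, x: Tensor, valid: np.ndarray):
        """x: (B, H, W, C_in) raster batch (image mode) or tile-feature
        grids (tile mode); ``valid`` is the shared h×w validity mask.
        Returns (list of 4 stage Tensors in grid form, pooled Tensor)."""
        if x.shape[1] < 1 or x.shape[2] < 1:
            raise ValueError("empty spatial input")
        if self.config.tokenizer_kind == "conv":
            if x.shape[1] < 4 or x.shape[2] < 4:
                raise ValueError("conv tokenizer needs spatial dims >= 4")
            x = self.tokenizer(x)
            valid = _pool_mask(_pool_mask(valid))
        else:
            x = self.tokenizer(x)
        maps = []
        x_grid = x
        for i, blocks in enumerate(self.stages):
            h, w = x_grid.shape[1], x_grid.shape[2]
            if h < 1 or w < 1 or not valid.any():
                raise ValueError(f"stage {i + 1} collapsed to zero valid extent")
            ctx = _GridCtx(h, w, valid)
            flat = ctx.to_flat(x_grid)
            for block in blocks:
                flat = block(flat, ctx)
            x_grid = ctx.to_grid(flat)
            maps.append(x_grid)
            if i < 3:
                x_grid = self.downsamplers[i](x_grid)
                valid = _pool_mask(valid)
                mask = np.where(valid, 1.0, 0.0)[None, :, :, None]
                x_grid = x_grid * mask
        pooled = self.norm(flat).mean(axis=1)  # masked GAP: flat holds valid tokens only
        return maps, pooled


class NatContextualizer(Module):
    """Constant-resolution NAT encoder for MIL bags: a 1×1 linear
    embedding followed by ``depth`` NAT blocks over the tile grid,
    producing one contextualized embedding per tile (no downsampling, so
    tile identity is preserved for attention pooling)."""

    def __init__(self, d_in: int, dim: int, depth: int, heads: int, k: int,
                 mlp_ratio: float, layer_scale_init: float,
                 rng: np.random.Generator, mixer: str = "neighborhood"):
        self.embed = Linear(d_in, dim, rng)
        self.blocks = [NatBlock(dim, heads, k, mlp_ratio, layer_scale_init,
                                rng, mixer=mixer) for _ in range(depth)]
        self.norm = LayerNorm(dim)
        self.dim = dim

    def __call__(self, x: Tensor, ctx: _GridCtx):
        """x: (B, n, d_in) flat valid tiles. Returns (embedded, context)."""
        emb = self.embed(x)
        y = emb
        for block in self.blocks:
            y = block(y, ctx)
        return emb, self.norm(y)


# ---------------------------------------------------------------------------
# functional wrappers (numpy in / numpy out)

def tokenize(X, tokenizer) -> GridFeatureMap:
    """Run a tokenizer over a raster (h×w×c ndarray) or GridFeatureMap."""
    if isinstance(X, GridFeatureMap):
        arr, valid = X.X, X.valid
    else:
        arr = np.asarray(X, dtype=np.float64)
        valid = np.ones(arr.shape[:2], dtype=bool)
    out = tokenizer(Tensor(arr[None]))
    if isinstance(tokenizer, ConvTokenizer):
        valid = _pool_mask(_pool_mask(valid))
    out_arr = out.data[0] * np.where(valid, 1.0, 0.0)[:, :, None]
    return GridFeatureMap(out_arr, valid)


def nat_block(X: GridFeatureMap, block: NatBlock) -> GridFeatureMap:
    h, w, _ = X.shape
    ctx = _GridCtx(h, w, X.valid)
    flat = Tensor(X.flat_valid()[None])
    out = block(flat, ctx)
    return X.scatter(out.data[0])


def downsample(X: GridFeatureMap, ds: Downsampler) -> GridFeatureMap:
    out = ds(Tensor(X.X[None]))
    valid = _pool_mask(X.valid)
    out_arr = out.data[0] * np.where(valid, 1.0, 0.0)[:, :, None]
    return GridFeatureMap(out_arr, valid)


def forward_backbone(X, model: NatBackbone):
    """Spec-level forward: accepts a raster array (image mode) or a
    GridFeatureMap (tile mode); returns (StageOutput, pooled ndarray)."""
    if isinstance(X, GridFeatureMap):
        arr, valid = X.X, X.valid
    else:
        arr = np.asarray(X, dtype=np.float64)
        valid = np.ones(arr.shape[:2], dtype=bool)
    maps, pooled = model.forward(Tensor(arr[None]), valid)
    stage_valid = valid
    if model.config.tokenizer_kind == "conv":
        stage_valid = _pool_mask(_pool_mask(stage_valid))
    gmaps = []
    v = stage_valid
    for m in maps:
        gmaps.append(GridFeatureMap(m.data[0], v))
        v = _pool_mask(v)
    return StageOutput(maps=gmaps), pooled.data[0]
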