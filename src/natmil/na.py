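"""Sliding-neighborhood attention over a 2-D grid of token vectors.

Each query position attends to its ``k`` nearest *valid* grid positions
(Chebyshev distance, ties broken by Euclidean distance then raster
order), with a learned relative-positional bias added to every logit.
Near edges the neighbor set shifts inward, so every query keeps a
full-size attention span; with ``k`` equal to the number of valid
positions the operator coincides with global multi-head self-attention.

``oracle_masked_attention`` recomputes the same quantity as a dense
masked softmax over all positions and exists purely as a test oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nn import Module, trunc_normal
from ._tensor import Tensor

__all__ = [
    "GridFeatureMap",
    "NeighborhoodIndex",
    "NeighborhoodAttention",
    "build_neighborhood_index",
    "neighborhood_attention",
    "oracle_masked_attention",
    "global_self_attention",
    "table_radius",
]


@dataclass
class GridFeatureMap:
    """Dense h×w×c feature grid with a validity mask.

    Masked positions carry zeros and never act as keys or values.
    """

    X: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 3:
            raise ValueError("GridFeatureMap.X must be h×w×c")
        if self.valid is None:
            self.valid = np.ones(self.X.shape[:2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.X.shape[:2]:
            raise ValueError("valid mask must match spatial dims")

    @property
    def shape(self):
        return self.X.shape

    def flat_valid(self) -> np.ndarray:
        """Features of valid positions in raster order, (n_valid, c)."""
        return self.X[self.valid]

    def scatter(self, values: np.ndarray) -> "GridFeatureMap":
        """New map with ``values`` placed at valid positions, zeros elsewhere."""
        out = np.zeros(self.X.shape[:2] + (values.shape[-1],), dtype=np.float64)
        out[self.valid] = values
        return GridFeatureMap(out, self.valid.copy())


@dataclass
class NeighborhoodIndex:
    """Per-query ordered neighbor lists over the valid positions of a grid."""

    k: int
    positions: np.ndarray  # (n, 2) valid positions, raster order
    neighbors: np.ndarray  # (n, k_eff) indices into `positions`
    grid_shape: tuple

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def k_eff(self) -> int:
        return self.neighbors.shape[1]

    @property
    def offsets(self) -> np.ndarray:
        """(n, k_eff, 2) signed (Δrow, Δcol) of each neighbor from its query."""
        return self.positions[self.neighbors] - self.positions[:, None, :]


def build_neighborhood_index(h: int, w: int, k: int, valid: np.ndarray | None = None) -> NeighborhoodIndex:
    """Brute-force k-nearest-valid-neighbor lists for every valid position.

    Distance rule: Chebyshev, ties by squared Euclidean, then raster
    order — for k = m² (odd m) this reproduces the centred m×m window at
    interior positions and shifts the window inward at edges.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    pos = np.argwhere(valid)
    n = len(pos)
    if n == 0:
        raise ValueError("no valid positions")
    k_eff = min(k, n)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} valid positions; clamped", stacklevel=2)
    d = pos[:, None, :] - pos[None, :, :]  # (n, n, 2)
    cheb = np.abs(d).max(axis=2)
    eucl2 = (d ** 2).sum(axis=2)
    raster = (pos[:, 0] * w + pos[:, 1])[None, :].repeat(n, axis=0)
    order = np.lexsort((raster, eucl2, cheb), axis=1)
    return NeighborhoodIndex(k=k, positions=pos, neighbors=order[:, :k_eff],
                             grid_shape=(h, w))


def table_radius(k: int) -> int:
    """Radius of the relative-offset bias table guaranteed to cover an
    interior query's k-neighborhood; edge-shifted offsets beyond it are
    clamped to the nearest tabulated offset."""
    return int(np.ceil(np.sqrt(k)))


class NeighborhoodAttention(Module):
    """Multi-head neighborhood attention with relative positional biases."""

    def __init__(self, dim: int, heads: int, k: int, rng: np.random.Generator,
                 qkv_bias: bool = True):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.k = dim, heads, k
        self.dh = dim // heads
        self.Wq = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wk = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wv = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.Wo = Tensor(trunc_normal(rng, (dim, dim)), requires_grad=True)
        self.bq = Tensor(np.zeros(dim), requires_grad=True) if qkv_bias else None
        self.bk = Tensor(np.zeros(dim), requires_grad=True) if qkv_bias else None
        self.bv = Tensor(np.zeros(dim), requires_grad=True) if qkv_bias else None
        self.bo = Tensor(np.zeros(dim), requires_grad=True)
        r = table_radius(k)
        self.radius = r
        self.bias_table = Tensor(np.zeros((heads, (2 * r + 1) ** 2)), requires_grad=True)

    def bias_index(self, index: NeighborhoodIndex) -> np.ndarray:
        """Flat table index per (query, neighbor), offsets clamped to the table."""
        r = self.radius
        off = np.clip(index.offsets, -r, r)
        return (off[..., 0] + r) * (2 * r + 1) + (off[..., 1] + r)

    def __call__(self, x: Tensor, index: NeighborhoodIndex) -> Tensor:
        """x: (B, n, dim) token features of the valid positions, raster order."""
        b, n, c = x.shape
        h, dh = self.heads, self.dh
        q = x @ self.Wq
        kk = x @ self.Wk
        v = x @ self.Wv
        if self.bq is not None:
            q, kk, v = q + self.bq, kk + self.bk, v + self.bv
        q = q.reshape(b, n, h, 1, dh)
        kk = kk.reshape(b, n, h, dh)
        v = v.reshape(b, n, h, dh)
        nb = index.neighbors
        k_nb = kk[(slice(None), nb)].transpose(0, 1, 3, 4, 2)  # (B, n, h, dh, k)
        v_nb = v[(slice(None), nb)].transpose(0, 1, 3, 2, 4)   # (B, n, h, k, dh)
        logits = (q @ k_nb).reshape(b, n, h, index.k_eff) * float(1.0 / np.sqrt(dh))
        bias = self.bias_table[(slice(None), self.bias_index(index))]  # (h, n, k)
        logits = logits + bias.transpose(1, 0, 2)
        p = logits.softmax(axis=-1)                            # (B, n, h, k)
        out = p.reshape(b, n, h, 1, index.k_eff) @ v_nb        # (B, n, h, 1, dh)
        return out.reshape(b, n, c) @ self.Wo + self.bo

    def attention_weights(self, x: np.ndarray, index: NeighborhoodIndex) -> np.ndarray:
        """Softmax rows (n, k_eff, heads) for a single unbatched input."""
        x = np.asarray(x, dtype=np.float64)
        q = x @ self.Wq.data + (self.bq.data if self.bq is not None else 0.0)
        kk = x @ self.Wk.data + (self.bk.data if self.bk is not None else 0.0)
        n = x.shape[0]
        q = q.reshape(n, 1, self.heads, self.dh)
        kk = kk.reshape(n, self.heads, self.dh)
        logits = (q * kk[index.neighbors]).sum(-1) / np.sqrt(self.dh)
        logits += self.bias_table.data[:, self.bias_index(index)].transpose(1, 2, 0)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def neighborhood_attention(X: GridFeatureMap, params: NeighborhoodAttention,
                           k: int | None = None) -> GridFeatureMap:
    """Apply NA to a feature grid; masked positions output zero."""
    k = params.k if k is None else k
    h, w, _ = X.shape
    index = build_neighborhood_index(h, w, k, X.valid)
    flat = X.flat_valid()
    out = params(Tensor(flat[None]), index)
    return X.scatter(out.data[0])


def global_self_attention(x: np.ndarray, params: NeighborhoodAttention) -> np.ndarray:
    """Plain dense multi-head self-attention with the same projections,
    no positional bias. Reference for the k → n limit."""
    n, c = x.shape
    h, dh = params.heads, params.dh
    q = x @ params.Wq.data + (params.bq.data if params.bq is not None else 0.0)
    kk = x @ params.Wk.data + (params.bk.data if params.bk is not None else 0.0)
    v = x @ params.Wv.data + (params.bv.data if params.bv is not None else 0.0)
    q = q.reshape(n, h, dh).transpose(1, 0, 2)
    kk = kk.reshape(n, h, dh).transpose(1, 0, 2)
    v = v.reshape(n, h, dh).transpose(1, 0, 2)
    logits = q @ kk.transpose(0, 2, 1) / np.sqrt(dh)  # (h, n, n)
    z = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=2, keepdims=True)
    out = (p @ v).transpose(1, 0, 2).reshape(n, c)
    return out @ params.Wo.data + params.bo.data


def oracle_masked_attention(X: GridFeatureMap, params: NeighborhoodAttention,
                            index: NeighborhoodIndex) -> GridFeatureMap:
    """Dense n×n masked attention oracle: identical semantics to
    :func:`neighborhood_attention` computed the wasteful way."""
    flat = X.flat_valid()
    n, c = flat.shape
    h, dh = params.heads, params.dh
    q = flat @ params.Wq.data + (params.bq.data if params.bq is not None else 0.0)
    kk = flat @ params.Wk.data + (params.bk.data if params.bk is not None else 0.0)
    v = flat @ params.Wv.data + (params.bv.data if params.bv is not None else 0.0)
    q = q.reshape(n, h, dh).transpose(1, 0, 2)
    kk = kk.reshape(n, h, dh).transpose(1, 0, 2)
    v = v.reshape(n, h, dh).transpose(1, 0, 2)
    logits = q @ kk.transpose(0, 2, 1) / np.sqrt(dh)  # (h, n, n)
    bias = params.bias_table.data[:, params.bias_index(index)]  # (h, n, k)
    mask = np.full((n, n), -np.inf)
    rows = np.repeat(np.arange(n), index.k_eff)
    cols = index.neighbors.ravel()
    mask[rows, cols] = 0.0
    full_bias = np.zeros((h, n, n))
    full_bias[:, rows, cols] = bias.reshape(h, -1)
    logits = logits + mask[None] + full_bias
    z = logits - logits.max(axis=2, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=2, keepdims=True)
    out = (p @ v).transpose(1, 0, 2).reshape(n, c)
    out = out @ params.Wo.data + params.bo.data
    return X.scatter(out)
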