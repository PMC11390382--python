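"""Gated-attention pooling over tile embeddings and slide classification.

The bag embedding is an attention-weighted sum of contextualized tile
embeddings plus (optionally) the raw per-tile embeddings as a residual;
a linear class matrix maps it to slide scores, trained with
cross-entropy. Classic mean/max/gated-AB-MIL poolers are provided as
baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Linear, Module, trunc_normal
from ._tensor import Tensor
from .backbone import NatContextualizer, _GridCtx

__all__ = [
    "GatedAttentionPool", "SlidePrediction", "NatMilModel", "BaselineMilModel",
    "gated_attention", "aggregate_bag", "classify", "baseline_pool",
]


@dataclass
class SlidePrediction:
    slide_id: str
    g: np.ndarray            # bag embedding (d,)
    attention: np.ndarray    # per-tile weights, sums to 1
    y_pred: np.ndarray       # class scores (c,)
    probabilities: np.ndarray


class GatedAttentionPool(Module):
    """Scores s_i = wᵀ(tanh(V tᵢᵀ) ⊙ sigm(U tᵢᵀ)), softmaxed over the bag."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator):
        self.V = Tensor(trunc_normal(rng, (hidden, d), sd=0.1), requires_grad=True)
        self.U = Tensor(trunc_normal(rng, (hidden, d), sd=0.1), requires_grad=True)
        self.w = Tensor(trunc_normal(rng, (hidden, 1), sd=0.1), requires_grad=True)

    def scores(self, T: Tensor) -> Tensor:
        """T: (..., n, d) -> raw gate scores (..., n)."""
        gated = (T @ self.V.transpose(1, 0)).tanh() * (T @ self.U.transpose(1, 0)).sigmoid()
        s = gated @ self.w
        return s.reshape(s.shape[:-1])

    def __call__(self, T: Tensor) -> Tensor:
        return self.scores(T).softmax(axis=-1)


def gated_attention(T: np.ndarray, params: GatedAttentionPool) -> np.ndarray:
    """Attention weights for one bag (n×d array); permutation-equivariant."""
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] < 1:
        raise ValueError("T must be n×d with n >= 1")
    return params(Tensor(T)).data


def aggregate_bag(T_raw: np.ndarray, T_ctx: np.ndarray, a: np.ndarray) -> np.ndarray:
    """g = Σᵢ aᵢ (t_ctx,i + t_raw,i)."""
    T_raw = np.asarray(T_raw, dtype=np.float64)
    T_ctx = np.asarray(T_ctx, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if T_raw.shape[0] == 0:
        raise ValueError("empty bag")
    if T_raw.shape != T_ctx.shape or a.shape[0] != T_raw.shape[0]:
        raise ValueError("shape mismatch")
    return a @ (T_ctx + T_raw)


def classify(g: np.ndarray, W_c: np.ndarray):
    """y_pred = W_c gᵀ; probabilities via softmax."""
    g = np.asarray(g, dtype=np.float64).reshape(-1)
    W_c = np.asarray(W_c, dtype=np.float64)
    y = W_c @ g
    z = y - y.max()
    e = np.exp(z)
    return y, e / e.sum()


def baseline_pool(T: np.ndarray, mode: str,
                  params: GatedAttentionPool | None = None) -> np.ndarray:
    """Permutation-invariant bag pooling: 'max' (elementwise), 'mean',
    or 'abmil_gated' (gated attention weights, no contextual term)."""
    T = np.asarray(T, dtype=np.float64)
    if T.shape[0] < 1:
        raise ValueError("empty bag")
    if mode == "max":
        return T.max(axis=0)
    if mode == "mean":
        return T.mean(axis=0)
    if mode == "abmil_gated":
        if params is None:
            raise ValueError("abmil_gated needs GatedAttentionPool params")
        a = gated_attention(T, params)
        return a @ T
    raise ValueError(f"unknown mode {mode!r}; valid: max|mean|abmil_gated")


class NatMilModel(Module):
    """Neighborhood-context MIL classifier over tile-feature bags.

    Flags: ``residual_raw`` adds the raw tile embedding into the
    attention-weighted sum; ``gate_input`` selects whether the gate sees
    the contextualized ('context') or raw ('raw') embeddings.
    """

    def __init__(self, d_in: int, dim: int, n_classes: int = 2, depth: int = 2,
                 heads: int = 2, k: int = 9, mlp_ratio: float = 3.0,
                 layer_scale_init: float = 0.1, gate_hidden: int = 256,
                 mixer: str = "neighborhood", residual_raw: bool = True,
                 gate_input: str = "context", seed: int = 0):
        if gate_input not in ("context", "raw"):
            raise ValueError("gate_input must be 'context' or 'raw'")
        rng = np.random.default_rng(seed)
        self.context = NatContextualizer(d_in, dim, depth, heads, k, mlp_ratio,
                                         layer_scale_init, rng, mixer=mixer)
        self.pool = GatedAttentionPool(dim, gate_hidden, rng)
        self.classifier = Linear(dim, n_classes, rng, bias=False)
        self.residual_raw = residual_raw
        self.gate_input = gate_input

    def forward(self, x: Tensor, ctx: _GridCtx):
        """x: (B, n, d_in) bags on a shared grid. Returns (logits, a, g)."""
        emb, ctxe = self.context(x, ctx)
        gate_src = ctxe if self.gate_input == "context" else emb
        a = self.pool(gate_src)                      # (B, n)
        combined = ctxe + emb if self.residual_raw else ctxe
        b, n, d = combined.shape
        g = (a.reshape(b, n, 1) * combined).sum(axis=1)
        return self.classifier(g), a, g


class BaselineMilModel(Module):
    """Context-free MIL baselines: linear tile embedding then mean, max,
    or gated-AB-MIL pooling, then a linear classifier."""

    def __init__(self, d_in: int, dim: int, mode: str, n_classes: int = 2,
                 gate_hidden: int = 256, seed: int = 0):
        if mode not in ("mean", "max", "abmil_gated"):
            raise ValueError(f"unknown mode {mode!r}")
        rng = np.random.default_rng(seed)
        self.embed = Linear(d_in, dim, rng)
        self.mode = mode
        self.pool = GatedAttentionPool(dim, gate_hidden, rng) if mode == "abmil_gated" else None
        self.classifier = Linear(dim, n_classes, rng, bias=False)

    def forward(self, x: Tensor, ctx=None):
        emb = self.embed(x).gelu()
        if self.mode == "mean":
            g = emb.mean(axis=1)
            a = None
        elif self.mode == "max":
            g = emb.max(axis=1)
            a = None
        else:
            a = self.pool(emb)
            b, n, d = emb.shape
            g = (a.reshape(b, n, 1) * emb).sum(axis=1)
        return self.classifier(g), a, g
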