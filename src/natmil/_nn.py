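"""Small neural-network layer zoo on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = [
    "Module", "Linear", "LayerNorm", "Mlp", "Conv2d", "AdamW",
    "trunc_normal", "cross_entropy",
]


def trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02) -> np.ndarray:
    """Normal(0, sd) clipped at two standard deviations."""
    return np.clip(rng.normal(0.0, sd, size=shape), -2 * sd, 2 * sd)


class Module:
    """Parameter container with recursive discovery, pytorch-flavoured."""

    def parameters(self):
        out = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.data.shape)

    def named_parameters(self, prefix=""):
        items = []
        for key, value in vars(self).items():
            items.extend(_collect_named(value, f"{prefix}{key}"))
        return items

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name):
    if isinstance(value, Tensor) and value.requires_grad:
        return [(name, value)]
    if isinstance(value, Module):
        return value.named_parameters(prefix=name + ".")
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_collect_named(v, f"{name}.{i}"))
        return out
    return []


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, sd: float | None = None):
        # default: transformer-style truncated normal; pass sd for He-like scaling
        self.weight = Tensor(trunc_normal(rng, (d_in, d_out), sd=sd or 0.02),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Mlp(Module):
    """Two-layer perceptron with GELU, the transformer feed-forward."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Conv2d(Module):
    """Channels-last 2-D convolution via im2col gather + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, depthwise: bool = False):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out, self.depthwise = c_in, c_out, depthwise
        if depthwise:
            if c_out != c_in:
                raise ValueError("depthwise conv requires c_out == c_in")
            self.weight = Tensor(trunc_normal(rng, (kernel * kernel, c_in),
                                              sd=float(np.sqrt(2.0 / kernel ** 2))),
                                 requires_grad=True)
        else:
            self.weight = Tensor(trunc_normal(rng, (kernel * kernel * c_in, c_out),
                                              sd=float(np.sqrt(2.0 / (kernel ** 2 * c_in)))),
                                 requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def out_size(self, h: int, w: int):
        k, s, p = self.kernel, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, H, W, C)
        b, h, w, c = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        oh, ow = self.out_size(h, w)
        xp = x.pad(((0, 0), (p, p), (p, p), (0, 0)))
        r0 = np.arange(oh)[:, None, None, None] * s + np.arange(k)[None, None, :, None]
        c0 = np.arange(ow)[None, :, None, None] * s + np.arange(k)[None, None, None, :]
        rows = np.broadcast_to(r0, (oh, ow, k, k))
        cols = np.broadcast_to(c0, (oh, ow, k, k))
        patches = xp[(slice(None), rows, cols, slice(None))]  # (B, oh, ow, k, k, C)
        if self.depthwise:
            col = patches.reshape(b, oh, ow, k * k, c)
            y = (col * self.weight.reshape(1, 1, 1, k * k, c)).sum(axis=3)
        else:
            col = patches.reshape(b, oh, ow, k * k * c)
            y = col @ self.weight
        return y + self.bias


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean CE over the batch; labels are integer class ids."""
    logp = logits.log_softmax(axis=-1)
    n = logits.shape[0]
    picked = logp[(np.arange(n), np.asarray(labels, dtype=np.int64))]
    return -picked.mean()


class AdamW:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def cosine_schedule(step: int, total_steps: int, base_lr: float, warmup_frac: float = 0.1) -> float:
    """Linear warmup then cosine decay to zero."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    frac = (step - warmup) / max(1, total_steps - warmup)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * min(1.0, frac)))
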