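"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the models in this package need
(broadcast arithmetic, matmul, gather, pad, softmax/log-softmax,
pointwise nonlinearities, reductions). Gradients accumulate into
``Tensor.grad``; ``Tensor.backward()`` runs a topological sweep.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor", "use_dtype", "default_dtype"]

_DEFAULT_DTYPE = np.float64


def default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily set the dtype newly created tensors are cast to
    (float32 roughly halves training cost; float64 is the default)."""
    global _DEFAULT_DTYPE
    prev = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- helpers -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ----------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    # -- pointwise -----------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * val)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * (1.0 - val * val))
        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * val * (1.0 - val))
        out._backward = bw if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g * mask)
        out._backward = bw if out.requires_grad else None
        return out

    def gelu(self):
        # tanh approximation (field-standard)
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        val = 0.5 * x * (1.0 + t)
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            dval = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * dinner
            self._accum(g * dval)
        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, _parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        hit = (self.data == val)
        hit = hit / hit.sum(axis=axis, keepdims=True)  # split ties evenly
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, self.requires_grad, _parents=(self,))

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(hit * gg)
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, _parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, _parents=(self,))

        def bw(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, key, g)
        out._backward = bw if out.requires_grad else None
        return out

    def pad(self, pad_width):
        """Zero-pad; ``pad_width`` as for ``np.pad``."""
        out = Tensor(np.pad(self.data, pad_width), self.requires_grad, _parents=(self,))
        slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, self.data.shape))

        def bw(g):
            self._accum(g[slices])
        out._backward = bw if out.requires_grad else None
        return out

    # -- stable softmax family ----------------------------------------
    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            dot = (g * val).sum(axis=axis, keepdims=True)
            self._accum(val * (g - dot))
        out._backward = bw if out.requires_grad else None
        return out

    def log_softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        val = z - lse
        out = Tensor(val, self.requires_grad, _parents=(self,))

        def bw(g):
            self._accum(g - np.exp(val) * g.sum(axis=axis, keepdims=True))
        out._backward = bw if out.requires_grad else None
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bw if out.requires_grad else None
    return out
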