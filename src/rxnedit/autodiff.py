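"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The training stack needs differentiable message passing, Sinkhorn scaling and
the multi-task losses.  No deep-learning framework is assumed at runtime, so
this module provides a small vectorized tape: a :class:`Tensor` wrapping an
``ndarray``, the operations the model requires (broadcasting arithmetic,
matmul, exp/log/sigmoid/relu, reductions, row gather and segment sums for
graph aggregation), and an AdamW optimizer.

Everything runs in float64; desk-scale graphs make the extra precision cheap
and finite-difference gradient checks tight.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "gather_rows",
    "gather2d",
    "segment_sum",
    "softmax",
    "exp",
    "log",
    "clip",
    "total_sum",
    "mean",
    "AdamW",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = _parents

    # ---------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad))
        if req:
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out = self._make(self.data + other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data * other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out = self._make(self.data / other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data ** 2))

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data ** p, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = self._make(self.data @ other.data, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = backward
        return out

    def __rmatmul__(self, other):
        return self._wrap(other) @ self

    @property
    def T(self) -> "Tensor":
        out = self._make(self.data.T, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out = self._make(self.data.reshape(*shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        out._backward = backward
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = self._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = self._make(np.log(self.data), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = self._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through inside [lo, hi], zero outside."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = backward
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g, dtype=np.float64)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accum(np.broadcast_to(g, shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- backward
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    """Fan-in scaled random parameter."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


# --------------------------------------------------------------- structured ops
def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req,
                 _parents=tuple(t for t in tensors if t.requires_grad))
    if req:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(a, b)
                    t._accum(g[tuple(sl)])

        out._backward = backward
    return out


def gather_rows(t: Tensor, idx) -> Tensor:
    """Select rows t[idx]; repeated indices accumulate gradient."""
    idx = np.asarray(idx, dtype=np.intp)
    out = t._make(t.data[idx], (t,), None)

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accum(full)

    out._backward = backward
    return out


def gather2d(t: Tensor, rows, cols) -> Tensor:
    """Select entries t[rows[k], cols[k]] as a vector."""
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out = t._make(t.data[rows, cols], (t,), None)

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, (rows, cols), g)
            t._accum(full)

    out._backward = backward
    return out


def segment_sum(t: Tensor, idx, n: int) -> Tensor:
    """Sum rows of t into n buckets given per-row bucket indices (GNN aggregation)."""
    idx = np.asarray(idx, dtype=np.intp)
    data = np.zeros((n,) + t.data.shape[1:], dtype=np.float64)
    np.add.at(data, idx, t.data)
    out = t._make(data, (t,), None)

    def backward(g):
        if t.requires_grad:
            t._accum(g[idx])

    out._backward = backward
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max: value unchanged, gradients identical
    shift = Tensor(t.data.max(axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -------------------------------------------------- generic numpy/Tensor helpers
def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def clip(x, lo, hi):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def total_sum(x):
    return x.sum() if isinstance(x, Tensor) else np.sum(x)


def mean(x):
    return x.mean() if isinstance(x, Tensor) else np.mean(x)


# ---------------------------------------------------------------------- optimizer
class AdamW:
    """AdamW with decoupled weight decay over a dict of named parameters."""

    def __init__(self, params: dict, lr: float = 1e-4, weight_decay: float = 5e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8, no_decay: set | None = None):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.no_decay = no_decay or set()
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            if self.weight_decay and k not in self.no_decay:
                p.data *= (1 - self.lr * self.weight_decay)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def grad_check(fn, tensors: list[Tensor], h: float = 1e-6) -> float:
    """Max abs difference between analytic and central-difference gradients."""
    out = fn()
    out.backward()
    analytic = [t.grad.copy() if t.grad is not None else np.zeros_like(t.data)
                for t in tensors]
    worst = 0.0
    for t, a in zip(tensors, analytic):
        flat = t.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            hi = fn().item()
            flat[i] = orig - h
            lo = fn().item()
            flat[i] = orig
            num[i] = (hi - lo) / (2 * h)
        worst = max(worst, float(np.abs(num - a.ravel()).max()))
    return worst
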