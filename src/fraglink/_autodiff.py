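"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (a few graph-convolution layers and
two-hidden-layer MLPs on molecules of ~20 atoms), so a compact tape-based
engine is sufficient: `Tensor` wraps a float64 ndarray, records parents and
a backward closure per operation, and `backward()` runs the tape in reverse
topological order. Broadcasting follows numpy; gradients are summed back to
the parent's shape.

Only the operations the model needs are provided: arithmetic, matmul, relu,
exp, sum/mean, concatenation, row gathering, and fused layer-norm and
log-softmax (the latter mask-aware, treating -inf logits as excluded).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "layer_norm", "log_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autodiff core ---------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ---- operations ------------------------------------------------------
    def _track(self, out: "Tensor", parents, backward) -> "Tensor":
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        return self._track(out, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)

        def bw(g):
            self._accumulate(-g)

        return self._track(out, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        return self._track(out, (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return self._track(out, (self, other), bw)

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))

        def bw(g):
            self._accumulate(g * (self.data > 0.0))

        return self._track(out, (self,), bw)

    def exp(self):
        out = Tensor(np.exp(self.data))

        def bw(g):
            self._accumulate(g * out.data)

        return self._track(out, (self,), bw)

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._track(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape))

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._track(out, (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return tensors[0]._track(out, tuple(tensors), bw)


def gather_rows(t: Tensor, idx) -> Tensor:
    """Select rows of a 2-D tensor (duplicates allowed; grads accumulate)."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx])

    def bw(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accumulate(full)

    return t._track(out, (t,), bw)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gain.data + bias.data)
    n = x.data.shape[-1]

    def bw(g):
        bias._accumulate(g.reshape(-1, n).sum(axis=0))
        gain._accumulate((g * xhat).reshape(-1, n).sum(axis=0))
        gx = g * gain.data
        # d xhat / dx backprop in closed form
        dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
        x._accumulate(dx)

    return x._track(out, (x, gain, bias), bw)


def log_softmax(x: Tensor) -> Tensor:
    """Log-softmax over the last axis; -inf entries are masked out exactly."""
    d = x.data
    finite = np.isfinite(d)
    m = np.max(np.where(finite, d, -np.inf), axis=-1, keepdims=True)
    shifted = np.where(finite, d - m, -np.inf)
    expv = np.where(finite, np.exp(shifted), 0.0)
    total = expv.sum(axis=-1, keepdims=True)
    out = Tensor(np.where(finite, shifted - np.log(total), -np.inf))
    soft = expv / total

    def bw(g):
        g = np.where(finite, g, 0.0)
        x._accumulate(g - soft * g.sum(axis=-1, keepdims=True))

    return x._track(out, (x,), bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None,
           relu: bool = False) -> Tensor:
    """Fused affine map x @ w (+ b) with optional ReLU — one tape node."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    y = x.data @ w.data
    if b is not None:
        y = y + b.data
    if relu:
        y = np.maximum(y, 0.0)
    out = Tensor(y)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if relu:
            g = g * (y > 0.0)
        x._accumulate(g @ w.data.T)
        w._accumulate(x.data.T @ g)
        if b is not None:
            b._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))

    return x._track(out, parents, bw)


def const_matmul(a, h: Tensor) -> Tensor:
    """a @ h with a constant (possibly scipy-sparse) left factor."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    out = Tensor(np.asarray(a @ h.data))

    def bw(g):
        h._accumulate(np.asarray(a.T @ g))

    return h._track(out, (h,), bw)


def gcn_matmul(a: np.ndarray, h: Tensor, w: Tensor) -> Tensor:
    """Fused graph propagation a @ h @ w with a constant (dense or sparse)
    matrix `a`."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    ah = np.asarray(a @ h.data)
    out = Tensor(ah @ w.data)

    def bw(g):
        h._accumulate(np.asarray(a.T @ (g @ w.data.T)))
        w._accumulate(ah.T @ g)

    return h._track(out, (h, w), bw)


class Adam:
    """Adam with global gradient-norm clipping over a dict of parameters."""

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float = 5.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
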