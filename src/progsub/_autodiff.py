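"""Minimal reverse-mode automatic differentiation over dense numpy arrays.

Just enough machinery for the directed-graph encoders: dense/sparse matrix
products, elementwise arithmetic with broadcasting, rectifiers, exp/log,
reductions, row gathers and segment sums (for attention), and an Adam
optimizer.  Constant operands (numpy arrays, scipy sparse matrices, scalars)
may be mixed freely with parameters.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def backward(self):
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.value)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _make(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _make(a.value + b.value, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.value, a.shape))
        _accum(b, _unbroadcast(g * a.value, b.shape))

    return _make(a.value * b.value, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        _accum(a, g @ b.value.T)
        _accum(b, a.value.T @ g)

    return _make(a.value @ b.value, (a, b), backward)


def spmm(A: sp.spmatrix, x) -> Tensor:
    """Sparse constant matrix times dense tensor."""
    x = _wrap(x)
    A = A.tocsr()

    def backward(g):
        _accum(x, A.T @ g)

    return _make(A @ x.value, (x,), backward)


def relu(x) -> Tensor:
    x = _wrap(x)
    mask = x.value > 0

    def backward(g):
        _accum(x, g * mask)

    return _make(x.value * mask, (x,), backward)


def leaky_relu(x, alpha: float = 0.2) -> Tensor:
    x = _wrap(x)
    mask = x.value > 0
    slope = np.where(mask, 1.0, alpha)

    def backward(g):
        _accum(x, g * slope)

    return _make(x.value * slope, (x,), backward)


def exp(x) -> Tensor:
    x = _wrap(x)
    val = np.exp(x.value)

    def backward(g):
        _accum(x, g * val)

    return _make(val, (x,), backward)


def log(x) -> Tensor:
    x = _wrap(x)

    def backward(g):
        _accum(x, g / x.value)

    return _make(np.log(x.value), (x,), backward)


def power(x, p: float) -> Tensor:
    x = _wrap(x)

    def backward(g):
        _accum(x, g * p * np.power(x.value, p - 1))

    return _make(np.power(x.value, p), (x,), backward)


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = _wrap(x)

    def backward(g):
        if axis is None:
            _accum(x, np.broadcast_to(g, x.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            _accum(x, np.broadcast_to(gg, x.shape).copy())

    return _make(x.value.sum(axis=axis, keepdims=keepdims), (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets, offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _make(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), backward)


def gather_rows(x, idx: np.ndarray) -> Tensor:
    x = _wrap(x)
    idx = np.asarray(idx)

    def backward(g):
        gx = np.zeros_like(x.value)
        np.add.at(gx, idx, g)
        _accum(x, gx)

    return _make(x.value[idx], (x,), backward)


def segment_sum(x, idx: np.ndarray, n: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``n`` buckets given by ``idx``."""
    x = _wrap(x)
    idx = np.asarray(idx)

    def backward(g):
        _accum(x, g[idx])

    shape = (n,) + x.shape[1:]
    val = np.zeros(shape)
    np.add.at(val, idx, x.value)
    return _make(val, (x,), backward)


def softmax_rows(z) -> Tensor:
    """Row-wise softmax (numerically shifted by the detached row max)."""
    z = _wrap(z)
    shifted = add(z, Tensor(-z.value.max(axis=1, keepdims=True)))
    e = exp(shifted)
    return e / tsum(e, axis=1, keepdims=True)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
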