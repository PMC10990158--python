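"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the compression channels, decoders and set
predictors need: broadcasting arithmetic, batched matmul, smooth
nonlinearities, reductions, concatenation, row gathering and stable
softmax/log-softmax composites.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "gather_rows", "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents  # tuple of (Tensor, fn: g -> g_parent)
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, fn in t._parents:
                if not p.requires_grad:
                    continue
                gp = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + gp
                else:
                    grads[id(p)] = gp

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data + other.data,
            (
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, ((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data * other.data,
            (
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return Tensor(
            self.data / other.data,
            (
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        return Tensor(
            self.data**p,
            ((self, lambda g: g * p * self.data ** (p - 1)),),
        )

    def __matmul__(self, other):
        other = self._lift(other)

        def g_self(g):
            return _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.data.shape)

        def g_other(g):
            return _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.data.shape)

        return Tensor(np.matmul(self.data, other.data), ((self, g_self), (other, g_other)))

    # -------------------------------------------------------------- elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, ((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), ((self, lambda g: g / self.data),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, ((self, lambda g: g * (1.0 - out**2)),))

    def relu(self):
        mask = (self.data > 0).astype(np.float64)
        return Tensor(self.data * mask, ((self, lambda g: g * mask),))

    def softplus(self):
        out = np.logaddexp(self.data, 0.0)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(out, ((self, lambda g: g * sig),))

    def square(self):
        return Tensor(self.data**2, ((self, lambda g: g * 2.0 * self.data),))

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor(out, ((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), ((self, lambda g: g.reshape(old)),))

    def swaplast(self):
        """Swap the last two axes (for batched matmul transposes)."""
        return Tensor(
            np.swapaxes(self.data, -1, -2),
            ((self, lambda g: np.swapaxes(g, -1, -2)),),
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(
            np.transpose(self.data, axes),
            ((self, lambda g: np.transpose(g, inv)),),
        )

    def __getitem__(self, idx):
        def grad_fn(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], ((self, grad_fn),))


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors, axis=-1):
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
        def grad_fn(g, lo=lo, hi=hi):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            return g[tuple(sl)]

        parents.append((t, grad_fn))
    return Tensor(out, tuple(parents))


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows along axis 0; backward scatter-adds."""
    idx = np.asarray(idx)

    def grad_fn(g):
        out = np.zeros_like(t.data)
        np.add.at(out, idx, g)
        return out

    return Tensor(t.data[idx], ((t, grad_fn),))


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    # subtracting the (constant) max is gradient-exact for softmax
    m = Tensor(t.data.max(axis=axis, keepdims=True))
    z = t - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(t, axis=axis).exp()
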