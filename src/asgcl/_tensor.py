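"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs: broadcast arithmetic,
matrix products, reductions, pointwise nonlinearities, row gathers and
concatenation.  Gradients are accumulated by a topological backward sweep;
all arrays are float64 for deterministic single-threaded runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat_rows", "take_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray + Tensor defer to Tensor.__radd__ etc.
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad, (self,))
        out._backward = lambda g: (g.T,)
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: (_unbroadcast(g, self.shape),
                                   _unbroadcast(g, other.shape))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: (_unbroadcast(g * other.data, self.shape),
                                   _unbroadcast(g * self.data, other.shape))
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: (
            _unbroadcast(g / other.data, self.shape),
            _unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))
        out._backward = lambda g: (g @ other.data.T, self.data.T @ g)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise -------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * 0.5 / val,)
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: (g * val * (1.0 - val),)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    # -- autodiff driver -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                if parent._parents:
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg
                else:
                    parent.grad = pg if parent.grad is None else parent.grad + pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def take_rows(t: Tensor, idx) -> Tensor:
    """Gather rows by integer index; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(t.data[idx], t.requires_grad, (t,))

    def bwd(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)

    out._backward = bwd
    return out


def concat_rows(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(np.concatenate([a.data, b.data], axis=0),
                 a.requires_grad or b.requires_grad, (a, b))
    na = a.data.shape[0]
    out._backward = lambda g: (g[:na], g[na:])
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
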