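"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for convolutional image-to-image
networks: broadcast arithmetic, reductions, matmul, 2-D (transposed,
depthwise) convolution, pooling, bilinear resampling, embeddings and the
usual activations.  All data is float32; gradients are accumulated in
float32 as well.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_scalars"]


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_children")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) or any(c.requires_grad for c in _children)
        self.grad = None
        self._backward = _backward
        self._children = _children

    # ------------------------------------------------------------------ utils
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _acc(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=np.float32)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for c in t._children:
                if c.requires_grad:
                    visit(c)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _children=(self, other))

        def bw(g):
            self._acc(_unbroadcast(g, self.data.shape))
            other._acc(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _children=(self,))
        out._backward = lambda g: self._acc(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _children=(self, other))

        def bw(g):
            self._acc(_unbroadcast(g * other.data, self.data.shape))
            other._acc(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, _children=(self, other))

        def bw(g):
            self._acc(_unbroadcast(g / other.data, self.data.shape))
            other._acc(_unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def pow(self, p: float):
        out = Tensor(self.data ** p, _children=(self,))
        out._backward = lambda g: self._acc(g * p * self.data ** (p - 1))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _children=(self,))
        out._backward = lambda g: self._acc(g * 0.5 / np.maximum(np.sqrt(self.data), 1e-12))
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _children=(self,))
        out._backward = lambda g: self._acc(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _children=(self,))
        out._backward = lambda g: self._acc(g / self.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _children=(self,))
        out._backward = lambda g: self._acc(g * np.sign(self.data))
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _children=(self,))

        def bw(g):
            if axis is None:
                self._acc(np.broadcast_to(g, self.data.shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._acc(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _children=(self,))
        out._backward = lambda g: self._acc(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _children=(self,))
        out._backward = lambda g: self._acc(g.transpose(tuple(inv)))
        return out

    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _children=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._acc(_unbroadcast(ga, a.shape))
            other._acc(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # ------------------------------------------------------------ activations
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _children=(self,))
        out._backward = lambda g: self._acc(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _children=(self,))
        out._backward = lambda g: self._acc(g * np.where(self.data > 0, 1.0, slope))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _children=(self,))
        out._backward = lambda g: self._acc(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _children=(self,))
        out._backward = lambda g: self._acc(g * out.data * (1.0 - out.data))
        return out

    def hardsigmoid(self):
        y = np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)
        out = Tensor(y, _children=(self,))
        out._backward = lambda g: self._acc(g * ((self.data > -3) & (self.data < 3)) / 6.0)
        return out

    def hardswish(self):
        return self * self.hardsigmoid()

    def softplus(self):
        # numerically stable: log(1 + e^x) = max(x,0) + log1p(e^-|x|)
        y = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        out = Tensor(y, _children=(self,))
        out._backward = lambda g: self._acc(g / (1.0 + np.exp(-self.data)))
        return out

    def logsigmoid(self):
        return -((-self).softplus())


# ---------------------------------------------------------------------- joins

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _children=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._acc(g[tuple(idx)])

    out._backward = bw
    return out


def stack_scalars(tensors) -> Tensor:
    """Stack scalar tensors into a 1-D tensor (for weighted loss sums)."""
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.array([t.data.reshape(()) for t in tensors]), _children=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._acc(np.reshape(g[i], t.data.shape))

    out._backward = bw
    return out
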