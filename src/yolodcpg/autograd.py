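"""Reverse-mode automatic differentiation over NumPy arrays.

A compact tape-based autograd engine: every :class:`Tensor` wraps an
``ndarray`` and records the operations that produced it, so that
``Tensor.backward()`` accumulates gradients for every upstream tensor with
``requires_grad=True``.  Broadcasting follows NumPy semantics; gradients of
broadcast operands are reduced back to their original shape.

Only the operations needed by the detector stack are implemented (elementwise
arithmetic, exp/log/tanh/sqrt/clip, matmul, reshape/transpose/concat/slice,
reductions, sigmoid/softmax).  Convolution and pooling are built on top of
these plus two custom primitives in :mod:`yolodcpg.nn`.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context (inference / profiling)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic introspection --------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def build(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            if not t._parents:  # leaves accumulate .grad
                t.grad = g if t.grad is None else t.grad + g
        # also store gradient on self if it is a leaf-like root
        if not self._parents and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor._make(self.data + other.data, (self, other),
                           lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor._make(self.data * other.data, (self, other),
                            lambda g: (_unbroadcast(g * other.data, self.shape),
                                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return Tensor._make(self.data / other.data, (self, other),
                            lambda g: (_unbroadcast(g / other.data, self.shape),
                                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, p: float):
        data = self.data ** p
        return Tensor._make(data, (self,), lambda g: (g * p * self.data ** (p - 1),))

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return Tensor._make(self.data[idx], (self,), bwd)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        return Tensor._make(data, (self,), lambda g: (g * data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        data = np.sqrt(self.data)
        return Tensor._make(data, (self,), lambda g: (g * 0.5 / data,))

    def tanh(self):
        data = np.tanh(self.data)
        return Tensor._make(data, (self,), lambda g: (g * (1.0 - data ** 2),))

    def sigmoid(self):
        data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(data, (self,), lambda g: (g * data * (1.0 - data),))

    def clip(self, lo, hi):
        mask = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
        return Tensor._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    def relu(self):
        mask = (self.data > 0).astype(self.data.dtype)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def maximum(self, other):
        other = astensor(other)
        mask = (self.data >= other.data).astype(self.data.dtype)
        return Tensor._make(np.maximum(self.data, other.data), (self, other),
                            lambda g: (_unbroadcast(g * mask, self.shape),
                                       _unbroadcast(g * (1 - mask), other.shape)))

    def minimum(self, other):
        other = astensor(other)
        mask = (self.data <= other.data).astype(self.data.dtype)
        return Tensor._make(np.minimum(self.data, other.data), (self, other),
                            lambda g: (_unbroadcast(g * mask, self.shape),
                                       _unbroadcast(g * (1 - mask), other.shape)))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other):
        other = astensor(other)
        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))
        return Tensor._make(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def stack(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(p.squeeze(axis=axis).reshape(t.shape) for p, t in zip(parts, tensors))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    c = np.asarray(cond)
    return Tensor._make(np.where(c, a.data, b.data), (a, b),
                        lambda g: (_unbroadcast(g * c, a.shape),
                                   _unbroadcast(g * (~c), b.shape)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = astensor(x)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
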