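"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the caption transcoder and the tiny CNN
backbone need: broadcasted arithmetic, batched matrix products, ReLU,
reshape/transpose, reductions, fused layer normalisation and softmax, an
embedding gather, and a fused masked sparse-categorical-cross-entropy head.
All gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bwd
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(old))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # -- nonlinearity and reductions ----------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- fused neural-net primitives ----------------------------------------
    def layer_norm(self, eps: float = 1e-6):
        """Normalise the last axis to zero mean, unit variance."""
        mu = self.data.mean(axis=-1, keepdims=True)
        var = self.data.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mu) * inv
        out = Tensor(xhat, (self,))

        def bwd(g):
            m1 = g.mean(axis=-1, keepdims=True)
            m2 = (g * xhat).mean(axis=-1, keepdims=True)
            self._accumulate(inv * (g - m1 - xhat * m2))

        out._backward = bwd
        return out

    def softmax(self):
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(y, (self,))

        def bwd(g):
            dot = (g * y).sum(axis=-1, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bwd
        return out

    def embedding(self, indices):
        """Row gather: ``self`` is a (V, D) table, ``indices`` any int array."""
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], (self,))

        def bwd(g):
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            np.add.at(self.grad, idx, g)

        out._backward = bwd
        return out


def cross_entropy_logits(logits: Tensor, labels, mask=None) -> Tensor:
    """Mean sparse categorical cross-entropy from raw scores.

    ``logits`` has shape (..., C); ``labels`` integer array of shape (...).
    Positions where ``mask`` is falsy are excluded from the mean.
    """
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - logsumexp
    if mask is None:
        mask = np.ones(labels.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    count = max(int(mask.sum()), 1)
    picked = np.take_along_axis(logp, labels[..., None], axis=-1)[..., 0]
    loss_val = -(picked * mask).sum() / count
    out = Tensor(loss_val, (logits,))

    def bwd(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
        grad = (p - onehot) * mask[..., None] / count
        logits._accumulate(grad * g)

    out._backward = bwd
    return out
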