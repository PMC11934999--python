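"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations needed to train the graph attention
autoencoder and the mapping matrix by gradient descent: dense matmul,
elementwise arithmetic with broadcasting, the activations used by the
models (sigmoid, ELU, exp, log, abs), axis reductions, row gathering and
segment sums (the scatter/gather pair behind per-neighborhood softmax),
plus an Adam optimizer.

Gradients are accumulated by a topological backward sweep over the tape.
All operations are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) else data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def matmul(self, other):
        other = Tensor._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:  # inner product -> scalar
                return (g * b, g * a)
            if a.ndim == 1:  # (k,) @ (k,m) -> (m,)
                return (g @ b.T, np.outer(a, g))
            if b.ndim == 1:  # (n,k) @ (k,) -> (n,)
                return (np.outer(g, b), a.T @ g)
            return (g @ b.T, a.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        expm = alpha * np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(pos, self.data, expm)

        def backward(g):
            return (g * np.where(pos, 1.0, expm + alpha),)

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)
        return self._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    # -- indexing / segment ops ----------------------------------------------
    def gather_rows(self, idx: np.ndarray):
        """Rows (or elements of a 1-D tensor) at integer positions `idx`."""
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            return (grad,)

        return self._make(out_data, (self,), backward)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int):
        """Sum entries (rows) sharing a segment id; inverse of gather_rows."""
        segment_ids = np.asarray(segment_ids)
        out_shape = (num_segments,) + self.data.shape[1:]
        out_data = np.zeros(out_shape, dtype=self.data.dtype)
        np.add.at(out_data, segment_ids, self.data)

        def backward(g):
            return (g[segment_ids],)

        return self._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    # -- composites -----------------------------------------------------------
    def softmax_rows(self):
        """Row-wise softmax of a 2-D tensor (max-shifted for stability)."""
        shift = self - Tensor(self.data.max(axis=1, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=1, keepdims=True)

    # -- backward sweep -------------------------------------------------------
    def backward(self):
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                # out-of-place accumulation: aliasing a returned view is safe
                parent.grad = g if parent.grad is None else parent.grad + g


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
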