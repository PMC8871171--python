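"""Minimal reverse-mode automatic differentiation on numpy arrays.

The popularity-prediction models in :mod:`spillcast.models` are small
message-passing networks whose forward passes are compositions of dense
linear maps, sparse-matrix products against a fixed adjacency structure,
row gathers along edge lists, and elementwise nonlinearities.  This module
provides exactly that operation set as a :class:`Tensor` wrapper with
reverse-mode gradients, which keeps the whole stack dependency-light and
CPU-friendly.

Conventions
-----------
* Leaf tensors created with ``requires_grad=True`` accumulate gradients in
  ``.grad`` after :meth:`Tensor.backward`.
* Broadcasting follows numpy; gradients are summed back over broadcast axes.
* Sparse operands (:func:`spmm`) are constants — only the dense side is
  differentiated.  That matches the models, where adjacency is data.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "tensor", "concat", "spmm", "gather", "scatter_add"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a reverse-mode gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff engine ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, expanded = stack.pop()
                if id(node) in seen:
                    continue
                if expanded:
                    seen.add(id(node))
                    topo.append(node)
                else:
                    stack.append((node, True))
                    for p in node._parents:
                        if id(p) not in seen:
                            stack.append((p, False))

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): _as_array(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if not (parent.requires_grad or parent._parents):
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg

    # -- arithmetic -----------------------------------------------------------
    def _binary(self, other, fwd, bwd):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data))
        out._parents = (self, other)
        a_shape, b_shape = self.data.shape, other.data.shape

        def backward(g):
            ga, gb = bwd(g, self.data, other.data)
            return ((self, _unbroadcast(ga, a_shape)), (other, _unbroadcast(gb, b_shape)))

        out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return other.__sub__(self)

    def __mul__(self, other):
        return self._binary(other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(
            other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return other.__truediv__(self)

    def __neg__(self):
        out = Tensor(-self.data)
        out._parents = (self,)
        out._backward = lambda g: ((self, -g),)
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p)
        out._parents = (self,)
        out._backward = lambda g: ((self, g * p * self.data ** (p - 1)),)
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data)
        out._parents = (self, other)

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                return ((self, g * b), (other, g * a))
            if a.ndim == 1:
                return ((self, g @ b.T), (other, np.outer(a, g)))
            if b.ndim == 1:
                return ((self, np.outer(g, b)), (other, a.T @ g))
            return ((self, g @ b.T), (other, a.T @ g))

        out._backward = backward
        return out

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape).copy()),)

        out._parents = (self,)
        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))
        out._parents = (self,)
        out._backward = lambda g: ((self, np.asarray(g).reshape(self.data.shape)),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        out._parents = (self,)
        out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: ((self, g * val),)
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        out._parents = (self,)
        out._backward = lambda g: ((self, g / self.data),)
        return out

    def sigmoid(self):
        x = self.data
        val = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: ((self, g * val * (1.0 - val)),)
        return out

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val)
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out._parents = (self,)
        out._backward = lambda g: ((self, g * sig),)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val)
        out._parents = (self,)
        out._backward = lambda g: ((self, g * (1.0 - val * val)),)
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask)
        out._parents = (self,)
        out._backward = lambda g: ((self, g * mask),)
        return out

    def clip(self, lo: float, hi: float):
        mask = ((self.data > lo) & (self.data < hi)).astype(np.float64)
        out = Tensor(np.clip(self.data, lo, hi))
        out._parents = (self,)
        out._backward = lambda g: ((self, g * mask),)
        return out


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    parts = [p if isinstance(p, Tensor) else Tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis))
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(np.asarray(g), splits, axis=axis)
        return tuple((p, piece) for p, piece in zip(parts, pieces))

    out._parents = tuple(parts)
    out._backward = backward
    return out


def spmm(A: sp.spmatrix, X: Tensor) -> Tensor:
    """Sparse @ dense product with gradient through the dense side only.

    ``A`` encodes graph structure (row-normalised adjacency, incidence maps)
    and is treated as a constant, so the per-layer cost is O(nnz(A)) —
    linear in the number of edges.
    """
    X = X if isinstance(X, Tensor) else Tensor(X)
    A = A.tocsr()
    out = Tensor(A @ X.data)
    out._parents = (X,)
    out._backward = lambda g: ((X, A.T @ np.asarray(g)),)
    return out


def gather(X: Tensor, index: np.ndarray) -> Tensor:
    """Row gather ``X[index]`` with scatter-add backward."""
    return X[np.asarray(index, dtype=np.intp)]


def scatter_add(values: Tensor, index: np.ndarray, n_rows: int) -> Tensor:
    """Segment sum: ``out[i] = sum(values[index == i])`` along axis 0."""
    index = np.asarray(index, dtype=np.intp)
    cols = values.data.shape[0]
    S = sp.csr_matrix(
        (np.ones(cols), (index, np.arange(cols))),
        shape=(n_rows, cols),
    )
    return spmm(S, values)
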