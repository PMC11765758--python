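"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional detectors on a single CPU; this
module provides the tensor abstraction and the primitive operations those
models need (broadcast arithmetic, matmul, pointwise nonlinearities,
reductions, shape surgery).  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward`, which walks a topological order of the recorded
graph.  Only the primitives used by the detector are implemented; each
backward rule is checked against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "maximum", "minimum", "where"]


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array-like, got Tensor")
    a = np.asarray(x, dtype=dtype)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = _as_array(data, dtype)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(p for p in parents if p.requires_grad) if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        topo, seen = [], set()
        stack = [self]
        while stack:  # iterative DFS: graphs can be deep
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()

        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and node._backward is None:
                    node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in node._backward(g):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
            if node is self or node._parents == ():
                node.grad = g if node.grad is None else node.grad + g
        # leaves visited above store their grad; interior nodes are transient

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data
        a, b = self, other

        def backward(g):
            return ((a, _unbroadcast(g, a.data.shape)),
                    (b, _unbroadcast(g, b.data.shape)))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-self.data, (a,), lambda g: ((a, -g),))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return (-self) + self._coerce(other)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data * b.data

        def backward(g):
            return ((a, _unbroadcast(g * b.data, a.data.shape)),
                    (b, _unbroadcast(g * a.data, b.data.shape)))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data / b.data

        def backward(g):
            return ((a, _unbroadcast(g / b.data, a.data.shape)),
                    (b, _unbroadcast(-g * out_data / b.data, b.data.shape)))

        return Tensor._make(out_data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            return ((a, g * p * a.data ** (p - 1)),)

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return ((a, _unbroadcast(ga, a.data.shape)),
                    (b, _unbroadcast(gb, b.data.shape)))

        return Tensor._make(out_data, (a, b), backward)

    # -- pointwise nonlinearities ---------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * out_data),))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: ((a, g / a.data),))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * 0.5 / out_data),))

    def sigmoid(self):
        a = self
        # evaluate on the negative half-line only: no overflow either side
        x = a.data
        pos = x >= 0
        e = np.exp(np.where(pos, -x, x))
        out_data = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))
        return Tensor._make(out_data, (a,),
                            lambda g: ((a, g * out_data * (1.0 - out_data)),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: ((a, g * mask),))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = (a.data > lo) & (a.data < hi)
        return Tensor._make(out_data, (a,), lambda g: ((a, g * mask),))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape surgery --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: ((a, g.reshape(old)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: ((a, g.transpose(inv)),))

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]

        def backward(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            return ((a, ga),)

        return Tensor._make(out_data.copy() if out_data.base is not None else out_data,
                            (a,), backward)


# -- free functions ------------------------------------------------------------

def concatenate(tensors, axis=0):
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors, axis=0):
    tensors = list(tensors)
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.reshape(t.data.shape)) for t, p in zip(tensors, parts))

    return Tensor._make(out_data, tuple(tensors), backward)


def maximum(a, b):
    """Elementwise max; on ties the gradient goes to the first argument."""
    if not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    b = a._coerce(b)
    out_data = np.maximum(a.data, b.data)
    mask = a.data >= b.data

    def backward(g):
        return ((a, _unbroadcast(g * mask, a.data.shape)),
                (b, _unbroadcast(g * (~mask), b.data.shape)))

    return Tensor._make(out_data, (a, b), backward)


def minimum(a, b):
    if not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    b = a._coerce(b)
    out_data = np.minimum(a.data, b.data)
    mask = a.data <= b.data

    def backward(g):
        return ((a, _unbroadcast(g * mask, a.data.shape)),
                (b, _unbroadcast(g * (~mask), b.data.shape)))

    return Tensor._make(out_data, (a, b), backward)


def where(cond: np.ndarray, a, b):
    """Select with a boolean numpy mask (no gradient through the mask)."""
    cond = np.asarray(cond, dtype=bool)
    if not isinstance(a, Tensor):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    b = a._coerce(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        return ((a, _unbroadcast(g * cond, a.data.shape)),
                (b, _unbroadcast(g * (~cond), b.data.shape)))

    return Tensor._make(out_data, (a, b), backward)
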