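"""A small reverse-mode automatic differentiation engine on numpy arrays.

The segmentation network in this package is built entirely on this module:
:class:`Tensor` wraps an ``ndarray`` together with an optional gradient and a
backward closure, and ``backward()`` walks the recorded graph in reverse
topological order.  Only the operations the model needs are implemented, and
each one is checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype new tensors are cast to (float64 default; training
    loops switch to float32 for speed)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


__all__ = [
    "Tensor",
    "set_default_dtype",
    "get_default_dtype",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "concat",
    "softmax",
    "relu",
    "sigmoid",
    "exp",
    "log",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in a dynamically recorded computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward
        self._grad_owned = False

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None
        self._grad_owned = False

    def _accumulate(self, g: np.ndarray):
        # keep a (possibly shared, read-only) reference until a second
        # contribution arrives, then materialize an owned buffer once
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + g
            self._grad_owned = True
        else:
            self.grad += g

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_DEFAULT_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * power(other, -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * power(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    def __pow__(self, p):
        return power(self, p)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _bw(g, self=self, src_shape=src_shape):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        out._backward = _bw if self.requires_grad else None
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def _bw(g, self=self, inv=inv):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = _bw if self.requires_grad else None
        return out

    def flip_hw(self):
        """Reverse the two trailing spatial axes (used by transposed conv)."""
        out = Tensor(self.data[..., ::-1, ::-1], self.requires_grad, (self,))

        def _bw(g, self=self):
            if self.requires_grad:
                self._accumulate(g[..., ::-1, ::-1])

        out._backward = _bw if self.requires_grad else None
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, self.requires_grad, (self,))

        def _bw(g, self=self, axis=axis, keepdims=keepdims):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.data.ndim for a in ax)
                g = np.expand_dims(g, ax)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw if self.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def power(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** p, a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    out._backward = _bw if a.requires_grad else None
    return out


def exp(a: Tensor) -> Tensor:
    e = np.exp(a.data)
    out = Tensor(e, a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * e)

    out._backward = _bw if a.requires_grad else None
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    out._backward = _bw if a.requires_grad else None
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    out._backward = _bw if a.requires_grad else None
    return out


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    e = np.exp(-np.abs(x))  # overflow-safe in both tails
    s = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = Tensor(s, a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    out._backward = _bw if a.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.matmul(a.data, b.data), a.requires_grad or b.requires_grad, (a, b))

    def _bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    out._backward = _bw if out.requires_grad else None
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad:
                t._accumulate(g[tuple(sl)])
            start += s

    out._backward = _bw if req else None
    return out


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` entries from ``start`` along ``axis``."""
    sl = [slice(None)] * a.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    out = Tensor(a.data[sl], a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            ga = np.zeros_like(a.data)
            ga[sl] = g
            a._accumulate(ga)

    out._backward = _bw if a.requires_grad else None
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, a.requires_grad, (a,))

    def _bw(g):
        if a.requires_grad:
            a._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = _bw if a.requires_grad else None
    return out
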