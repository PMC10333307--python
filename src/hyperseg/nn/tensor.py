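"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  Only the operations the
segmentation model needs are implemented; everything is dense, CPU and double
precision.  Broadcasting follows numpy semantics — gradients of broadcast
operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes that were prepended
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---------------------------------------------------------------- basics
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------- graph ops
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node._accum(g)
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                pg = _unbroadcast(pg, p.data.shape)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                elif p._backward is None:
                    p._accum(pg)
                else:
                    grads[id(p)] = pg

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data + other.data, (self, other),
                            lambda g: (g, g))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._make(self.data - other.data, (self, other),
                            lambda g: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(a * b, (self, other),
                            lambda g: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(a / b, (self, other),
                            lambda g: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        a = self.data
        return Tensor._make(a ** k, (self,),
                            lambda g: (g * k * a ** (k - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ga, gb

        return Tensor._make(a @ b, (self, other), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g / (2.0 * out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out * out),))

    def arctanh(self):
        a = self.data
        return Tensor._make(np.arctanh(a), (self,),
                            lambda g: (g / (1.0 - a * a),))

    def arcsinh(self):
        a = self.data
        return Tensor._make(np.arcsinh(a), (self,),
                            lambda g: (g / np.sqrt(1.0 + a * a),))

    def clip(self, lo=None, hi=None):
        a = self.data
        out = np.clip(a, lo, hi)
        inside = np.ones_like(a)
        if lo is not None:
            inside = inside * (a >= lo)
        if hi is not None:
            inside = inside * (a <= hi)
        return Tensor._make(out, (self,), lambda g: (g * inside,))

    def relu(self):
        a = self.data
        mask = a > 0
        return Tensor._make(a * mask, (self,), lambda g: (g * mask,))

    def abs(self):
        a = self.data
        s = np.sign(a)
        return Tensor._make(np.abs(a), (self,), lambda g: (g * s,))

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        a = self.data
        n = a.size if axis is None else (
            np.prod([a.shape[i] for i in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self.data
        return Tensor._make(a.reshape(shape), (self,),
                            lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def swapaxes(self, a1, a2):
        return Tensor._make(np.swapaxes(self.data, a1, a2), (self,),
                            lambda g: (np.swapaxes(g, a1, a2),))

    def __getitem__(self, idx):
        a = self.data

        def backward(g):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a[idx], (self,), backward)

    def pad(self, pad_width):
        a = self.data
        out = np.pad(a, pad_width)
        slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, a.shape))
        return Tensor._make(out, (self,), lambda g: (g[slices],))


class Parameter(Tensor):
    """A tensor that is optimized during training."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
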