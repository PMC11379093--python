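"""Reverse-mode automatic differentiation over numpy arrays.

A minimal define-by-run tape: every operation returns a new :class:`Tensor`
holding a closure that maps the output gradient to the parent gradients.
``Tensor.backward`` runs a topological sweep and accumulates gradients into
every node with ``requires_grad``.  Float64 throughout: the equation-level
oracle tests compare against explicit-loop references at tight tolerances.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy import special

__all__ = ["Tensor", "Parameter", "no_grad", "concat", "is_grad_enabled"]

_GRAD_ENABLED = [True]
_DEFAULT_DTYPE = [np.float64]


def default_dtype():
    return _DEFAULT_DTYPE[0]


def set_default_dtype(dtype):
    """Set the dtype new tensors are created with (float64 or float32).

    Float64 is the default and is what the equation-level oracle tests use;
    float32 roughly halves training time at a precision segmentation
    training does not need.
    """
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE[0] = dtype.type


@contextlib.contextmanager
def using_dtype(dtype):
    old = _DEFAULT_DTYPE[0]
    set_default_dtype(dtype)
    try:
        yield
    finally:
        _DEFAULT_DTYPE[0] = old


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / statistics updates)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE[0])
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
            out.requires_grad = any(p.requires_grad for p in parents)
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not (p.requires_grad or p._parents):
                    continue
                if p._backward is None and p.requires_grad:
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def back(g):
            # both operands are >= 2-D everywhere in this package
            da = g @ np.swapaxes(b.data, -1, -2)
            db = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(da, a.data.shape), _unbroadcast(db, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), back)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def back(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), back)

    def pad2d(self, ph: int, pw: int, value: float = 0.0):
        """Constant-pad the two trailing (spatial) axes."""
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(ph, ph), (pw, pw)]
        sl = tuple([slice(None)] * (a.ndim - 2) + [
            slice(ph, a.shape[-2] + ph), slice(pw, a.shape[-1] + pw)])
        return Tensor._make(
            np.pad(a.data, width, constant_values=value), (a,), lambda g: (g[sl],)
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sigmoid(self):
        a = self
        s = special.expit(a.data)
        return Tensor._make(s, (a,), lambda g: (g * s * (1.0 - s),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return Tensor._make(x * cdf, (a,), lambda g: (g * (cdf + x * pdf),))

    def softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def back(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._make(s, (a,), back)

    def log_softmax(self, axis=-1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        s = np.exp(ls)

        def back(g):
            return (g - s * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(ls, (a,), back)


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def back(g):
        outs = []
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            outs.append(g[tuple(sl)])
        return tuple(outs)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), back
    )
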