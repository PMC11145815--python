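"""Reverse-mode automatic differentiation over NumPy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
holding its value, its parents and a closure that propagates the upstream
gradient to those parents.  ``Tensor.backward()`` topologically sorts the
tape and accumulates ``.grad`` arrays on every tensor that requires them.

Only the operations needed by the affinity model live here (elementwise
arithmetic, matmul incl. batched, 1D convolution, sparse-dense matmul for
message passing, softmax, reductions, shape ops).  Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor", "tensor", "concat", "spmm", "conv1d", "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gdim, sdim) in enumerate(zip(grad.shape, shape)):
        if sdim == 1 and gdim != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- autograd ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in t._backward(g):
                if not (parent.requires_grad or parent._parents):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _needs(self, *others) -> bool:
        return any(t.requires_grad or t._parents for t in (self, *others))

    # -- elementwise arithmetic ---------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bw) \
            if self._needs(other) else Tensor(out_data)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            return ((self, -g),)
        return Tensor(-self.data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(-self.data)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bw(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bw) \
            if self._needs(other) else Tensor(out_data)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def bw(g):
            ga = _unbroadcast(g / other.data, self.data.shape)
            gb = _unbroadcast(-g * self.data / other.data ** 2,
                              other.data.shape)
            return ((self, ga), (other, gb))

        return Tensor(out_data, _parents=(self, other), _backward=bw) \
            if self._needs(other) else Tensor(out_data)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def bw(g):
            return ((self, g * e * self.data ** (e - 1.0)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    # -- matmul --------------------------------------------------------
    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def bw(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))

        return Tensor(out_data, _parents=(self, other), _backward=bw) \
            if self._needs(other) else Tensor(out_data)

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        out_data = np.maximum(self.data, 0)

        def bw(g):
            return ((self, g * (self.data > 0)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            return ((self, g * out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def log(self):
        def bw(g):
            return ((self, g / self.data),)
        out_data = np.log(self.data)
        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            return ((self, g * 0.5 / out_data),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def abs(self):
        out_data = np.abs(self.data)

        def bw(g):
            return ((self, g * np.sign(self.data)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if axis is None:
                return ((self, np.broadcast_to(g, shape).copy()),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
            return ((self, np.broadcast_to(g, shape).copy()),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            return ((self, g.reshape(orig)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            return ((self, g.transpose(inv)),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)

    def take_rows(self, idx: np.ndarray):
        """Row gather ``out[k] = self[idx[k]]`` along axis 0."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]
        shape = self.data.shape

        def bw(g):
            gx = np.zeros(shape, dtype=g.dtype)
            np.add.at(gx, idx, g)
            return ((self, gx),)

        return Tensor(out_data, _parents=(self,), _backward=bw) \
            if self._needs() else Tensor(out_data)


def tensor(data, requires_grad: bool = False, dtype=None) -> Tensor:
    arr = np.asarray(data, dtype=dtype)
    return Tensor(arr, requires_grad=requires_grad)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    if any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out_data, _parents=tuple(tensors), _backward=bw)
    return Tensor(out_data)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return ((x, out_data * (g - dot)),)

    return Tensor(out_data, _parents=(x,), _backward=bw) \
        if (x.requires_grad or x._parents) else Tensor(out_data)


def spmm(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse (constant) @ dense (differentiable): ``a @ x``."""
    a = a.tocsr()
    out_data = a @ x.data
    at = None

    def bw(g):
        nonlocal at
        if at is None:
            at = a.T.tocsr()
        return ((x, at @ g),)

    return Tensor(out_data, _parents=(x,), _backward=bw) \
        if (x.requires_grad or x._parents) else Tensor(out_data)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1D convolution, stride 1, 'same' zero padding (odd kernel).

    x: (B, C_in, L); w: (C_out, C_in, K); b: (C_out,) -> (B, C_out, L)
    """
    B, cin, L = x.data.shape
    cout, cin_w, K = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv1d channel mismatch: {cin} vs {cin_w}")
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel size")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # cols: (B, L, C_in * K)
    view = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    cols = view.transpose(0, 2, 1, 3).reshape(B, L, cin * K)
    wmat = w.data.reshape(cout, cin * K).T  # (C_in*K, C_out)
    out = cols @ wmat + b.data  # (B, L, C_out)
    out_data = out.transpose(0, 2, 1)

    def bw(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (B, L, C_out)
        gb = gt.sum(axis=(0, 1))
        gw = np.tensordot(gt, cols, axes=([0, 1], [0, 1])).reshape(
            cout, cin, K)
        gcols = gt @ wmat.T  # (B, L, C_in*K)
        gcols = gcols.reshape(B, L, cin, K).transpose(0, 2, 1, 3)
        gxp = np.zeros_like(xp)
        for k in range(K):
            gxp[:, :, k:k + L] += gcols[:, :, :, k]
        gx = gxp[:, :, pad:pad + L]
        return ((x, gx), (w, gw), (b, gb))

    if any(t.requires_grad or t._parents for t in (x, w, b)):
        return Tensor(out_data, _parents=(x, w, b), _backward=bw)
    return Tensor(out_data)
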