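"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the contrast module and the small
convolutional networks need: broadcast add/sub/mul, matmul, 2-D strided
convolution, ReLU, logistic sigmoid, reductions, reshape, and a
numerically stable softmax cross-entropy. All math is float64; the
networks involved are tiny, so clarity wins over throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "linear", "relu", "sigmoid", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless `grad` is given)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = parents
            out._backward = backward
        return out

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._lift(other)

        def back(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accumulate(-g)

        return Tensor._node(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._lift(other)

        def back(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._node(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __pow__(self, p):
        a = self
        p = float(p)

        def back(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._node(a.data**p, (a,), back)

    # -- shaping and reductions ------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def back(g):
            a._accumulate(g.reshape(orig))

        return Tensor._node(a.data.reshape(*shape), (a,), back)

    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def __matmul__(self, other):
        a, b = self, Tensor._lift(other)

        def back(g):
            a._accumulate(g @ b.data.T)
            b._accumulate(a.data.T @ g)

        return Tensor._node(a.data @ b.data, (a, b), back)


# -- nonlinearities -------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        x._accumulate(g * mask)

    return Tensor._node(x.data * mask, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    s = np.empty_like(x.data)
    pos = x.data >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    e = np.exp(x.data[~pos])
    s[~pos] = e / (1.0 + e)

    def back(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor._node(s, (x,), back)


# -- layers ---------------------------------------------------------------


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, F), w: (O, F), b: (O) -> (N, O)."""
    a, ww, bb = x, w, b

    def back(g):
        a._accumulate(g @ ww.data)
        ww._accumulate(g.T @ a.data)
        bb._accumulate(g.sum(axis=0))

    return Tensor._node(a.data @ ww.data.T + bb.data, (a, ww, bb), back)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation). x: (N,C,H,W), w: (O,C,kh,kw), b: (O)."""
    s, p = int(stride), int(padding)
    kh, kw = w.data.shape[2], w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s, :, :]  # (N, C, Ho, Wo, kh, kw)
    out = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True) + b.data[None, :, None, None]
    n, _, ho, wo = out.shape

    def back(g):
        w._accumulate(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
        b._accumulate(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                    "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                )
        x._accumulate(dxp[:, :, p : xp.shape[2] - p, p : xp.shape[3] - p] if p else dxp)

    return Tensor._node(out, (x, w, b), back)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. logits: (N, C); labels: int array (N,)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss = -logp[np.arange(n), labels].mean()

    def back(g):
        grad = np.exp(logp)
        grad[np.arange(n), labels] -= 1.0
        logits._accumulate(g * grad / n)

    return Tensor._node(loss, (logits,), back)
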