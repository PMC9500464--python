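"""Minimal reverse-mode automatic differentiation over numpy arrays.

The nested-autoencoder network in :mod:`gazenest.nested_ae` is small enough
(a few shallow convolutions and dense layers on 24x32 heatmaps) that CPU
numpy is ample; this module supplies exactly the operator set that network
needs -- dense/convolution/transposed-convolution layers, elementwise
nonlinearities, reductions and a softmax -- each with an analytic backward
pass. Gradients are exercised against central finite differences in the test
suite.

Tensors carry float64 (the default, used by the oracle and gradient-check
paths) or float32 (used for network training, where single precision is
ample and roughly halves memory traffic); python-scalar arithmetic never
upcasts, so a graph stays in the dtype of its leaves. All ops are
deterministic, so identical seeds give bitwise-identical results.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Adam",
    "matmul",
    "conv2d",
    "conv_transpose2d",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        tracked = tuple(p for p in parents if p.requires_grad or p._parents)
        if tracked:
            out.requires_grad = True
            out._parents = tracked
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.requires_grad or self._parents:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):  # scalar path: no upcast, no node
            def bws():
                self._accum(out.grad)

            out = Tensor._node(self.data + other, (self,), bws)
            return out
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def bw():
            self._accum(_unbroadcast(out.grad, self.data.shape))
            other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._node(out_data, (self, other), bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        def bw():
            self._accum(-out.grad)

        out = Tensor._node(-self.data, (self,), bw)
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bws():
                self._accum(out.grad * other)

            out = Tensor._node(self.data * other, (self,), bws)
            return out
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def bw():
            self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._node(out_data, (self, other), bw)
        return out

    __rmul__ = __mul__

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bw():
            self._accum(out.grad.reshape(src))

        out = Tensor._node(self.data.reshape(shape), (self,), bw)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._node(out_data, (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def bw():
            self._accum(out.grad * mask)

        out = Tensor._node(self.data * mask, (self,), bw)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw():
            self._accum(out.grad * s * (1.0 - s))

        out = Tensor._node(s, (self,), bw)
        return out

    def log(self):
        def bw():
            self._accum(out.grad / self.data)

        out = Tensor._node(np.log(self.data), (self,), bw)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bw():
            self._accum(out.grad * mask)

        out = Tensor._node(np.clip(self.data, lo, hi), (self,), bw)
        return out


# -- linear algebra ---------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product with gradients for both factors."""
    out_data = a.data @ b.data

    def bw():
        a._accum(out.grad @ b.data.T)
        b._accum(a.data.T @ out.grad)

    out = Tensor._node(out_data, (a, b), bw)
    return out


def softmax(logits: Tensor) -> Tensor:
    """Numerically stable softmax of a 1-D logit vector."""
    z = logits.data - logits.data.max()
    e = np.exp(z)
    s = e / e.sum()

    def bw():
        g = out.grad
        logits._accum(s * (g - float(np.dot(g, s))))

    out = Tensor._node(s, (logits,), bw)
    return out


# -- convolutions -----------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Cross-correlation of ``x`` (N,C,H,W) with ``w`` (F,C,kh,kw) plus bias.

    im2col is materialized contiguously once per call so both passes are
    plain BLAS matmuls; the backward input pass scatters the column
    gradients through the kh*kw kernel taps.
    """
    s, p = int(stride), int(padding)
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    f, _, kh, kw = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    # (N, Ho, Wo, C, kh, kw) -> contiguous (N*Ho*Wo, C*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, -1)
    wmat = wd.reshape(f, -1)
    out_data = (cols @ wmat.T).reshape(n, ho, wo, f).transpose(0, 3, 1, 2) + b.data[
        None, :, None, None
    ]

    def bw():
        g = out.grad
        b._accum(g.sum(axis=(0, 2, 3)))
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, f)
        w._accum((gmat.T @ cols).reshape(f, c, kh, kw))
        gcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        x._accum(gxp[:, :, p : p + h, p : p + wid] if p else gxp)

    out = Tensor._node(out_data, (x, w, b), bw)
    return out


def conv_transpose2d(
    x: Tensor,
    w: Tensor,
    b: Tensor,
    stride: int = 1,
    padding: int = 0,
    output_padding: int = 0,
) -> Tensor:
    """Transposed convolution: ``x`` (N,C,H,W), ``w`` (C,F,kh,kw).

    Output spatial size is ``(H-1)*stride - 2*padding + kh + output_padding``;
    ``output_padding`` must not exceed ``padding`` here (enough for the
    mirror-decoder geometry this package uses).
    """
    s, p, op = int(stride), int(padding), int(output_padding)
    if op > p:
        raise ValueError("output_padding must be <= padding in this implementation")
    xd, wd = x.data, w.data
    n, c, h, wid = xd.shape
    _, f, kh, kw = wd.shape
    full_h = (h - 1) * s + kh
    full_w = (wid - 1) * s + kw
    ho = full_h - 2 * p + op
    wo = full_w - 2 * p + op
    xmat = np.ascontiguousarray(xd.transpose(0, 2, 3, 1)).reshape(n * h * wid, c)
    # full-size scatter: the kernel taps are cheap slice adds
    out_full = np.zeros((n, f, full_h, full_w), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            tap = (xmat @ wd[:, :, i, j]).reshape(n, h, wid, f).transpose(0, 3, 1, 2)
            out_full[:, :, i : i + s * h : s, j : j + s * wid : s] += tap
    out_data = out_full[:, :, p : p + ho, p : p + wo] + b.data[None, :, None, None]

    def bw():
        g = out.grad
        b._accum(g.sum(axis=(0, 2, 3)))
        g_full = np.zeros((n, f, full_h, full_w), dtype=g.dtype)
        g_full[:, :, p : p + ho, p : p + wo] = g
        win = sliding_window_view(g_full, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        # win has exactly (h, wid) stride-s positions by construction
        gcols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * wid, f * kh * kw
        )
        wmat = wd.reshape(c, f * kh * kw)
        x._accum((gcols @ wmat.T).reshape(n, h, wid, c).transpose(0, 3, 1, 2))
        w._accum((xmat.T @ gcols).reshape(c, f, kh, kw))

    out = Tensor._node(out_data, (x, w, b), bw)
    return out


# -- optimizer --------------------------------------------------------------


class Adam:
    """Adam optimizer over a list of parameter Tensors (Kingma & Ba)."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
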