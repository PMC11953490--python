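"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ndarray and the
primitive operations needed by an encoder–decoder convolutional network and
its training losses (element-wise arithmetic with python-scalar fast paths,
reductions, stable sigmoid / softplus, stride-1 convolution via im2col, 2x2
transposed convolution, 2x2 max-pooling, concatenation, transpose and spatial
max). Gradients are accumulated by a topological sweep from the output; the
sweep frees the graph as it goes, so repeated training steps do not leave
reference cycles behind.

Convolutional ops use the channels-last (N, H, W, C) memory layout — the
layout in which im2col gathers and GEMM calls are contiguous on a CPU — while
parameter arrays keep the conventional (C_out, C_in, kh, kw) shape. Dtypes
are preserved end to end: float32 is the training precision, and float64
graphs are used by the finite-difference gradient checks.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "instance_norm",
    "maxpool2d",
    "spatial_max",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (forward passes become plain numpy)."""
    global _GRAD_ENABLED
    previous = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction ----------------------------------------------------

    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward_factory):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward_factory(out)
        return out

    def _accumulate(self, g) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            else:
                self.grad += g

    def backward(self, grad: np.ndarray | None = None, free_graph: bool = True) -> None:
        """Backpropagate from this tensor (seed defaults to ones).

        With ``free_graph`` (default) the graph is dismantled during the
        sweep: intermediate gradients and parent links are dropped, leaving
        gradients only on leaf tensors.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
            if free_graph and node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None if node is not self else node.grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _scalar(self, s: float, kind: str) -> "Tensor":
        """Fast path for python-scalar arithmetic; preserves dtype."""
        a = self
        if kind == "add":
            data = a.data + a.data.dtype.type(s)

            def factory(out):
                def backward():
                    a._accumulate(out.grad)
                return backward
        elif kind == "mul":
            data = a.data * a.data.dtype.type(s)

            def factory(out):
                def backward():
                    a._accumulate(out.grad * s)
                return backward
        elif kind == "rsub":
            data = a.data.dtype.type(s) - a.data

            def factory(out):
                def backward():
                    a._accumulate(-out.grad)
                return backward
        else:
            raise ValueError(kind)
        return Tensor._result(data, (a,), factory)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar(other, "add")
        other = self._wrap(other)
        a, b = self, other

        def factory(out):
            def backward():
                a._accumulate(_unbroadcast(out.grad, a.data.shape))
                b._accumulate(_unbroadcast(out.grad, b.data.shape))
            return backward

        return Tensor._result(a.data + b.data, (a, b), factory)

    __radd__ = __add__

    def __neg__(self):
        return self._scalar(-1.0, "mul")

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar(-other, "add")
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar(other, "rsub")
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar(other, "mul")
        other = self._wrap(other)
        a, b = self, other

        def factory(out):
            def backward():
                a._accumulate(_unbroadcast(out.grad * b.data, a.data.shape))
                b._accumulate(_unbroadcast(out.grad * a.data, b.data.shape))
            return backward

        return Tensor._result(a.data * b.data, (a, b), factory)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar(1.0 / other, "mul")
        other = self._wrap(other)
        a, b = self, other

        def factory(out):
            def backward():
                a._accumulate(_unbroadcast(out.grad / b.data, a.data.shape))
                b._accumulate(
                    _unbroadcast(-out.grad * a.data / (b.data * b.data), b.data.shape)
                )
            return backward

        return Tensor._result(a.data / b.data, (a, b), factory)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self

        def factory(out):
            def backward():
                a._accumulate(out.grad * exponent * a.data ** (exponent - 1))
            return backward

        return Tensor._result(a.data ** exponent, (a,), factory)

    # -- element-wise nonlinearities ------------------------------------------------

    def exp(self):
        a = self
        data = np.exp(a.data)

        def factory(out):
            d = data

            def backward():
                a._accumulate(out.grad * d)
            return backward

        return Tensor._result(data, (a,), factory)

    def log(self):
        a = self

        def factory(out):
            def backward():
                a._accumulate(out.grad / a.data)
            return backward

        return Tensor._result(np.log(a.data), (a,), factory)

    def sqrt(self):
        a = self
        data = np.sqrt(a.data)

        def factory(out):
            d = data

            def backward():
                a._accumulate(out.grad * (0.5 / d))
            return backward

        return Tensor._result(data, (a,), factory)

    def relu(self):
        a = self
        mask = a.data > 0

        def factory(out):
            def backward():
                a._accumulate(out.grad * mask)
            return backward

        return Tensor._result(np.where(mask, a.data, a.data.dtype.type(0)), (a,), factory)

    def sigmoid(self):
        a = self
        data = _stable_sigmoid(a.data).astype(a.data.dtype, copy=False)

        def factory(out):
            s = data

            def backward():
                a._accumulate(out.grad * s * (1.0 - s))
            return backward

        return Tensor._result(data, (a,), factory)

    def softplus(self):
        """Numerically stable log(1 + exp(x)); gradient is sigmoid(x)."""
        a = self
        x = a.data
        data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))

        def factory(out):
            def backward():
                a._accumulate(out.grad * _stable_sigmoid(x))
            return backward

        return Tensor._result(data, (a,), factory)

    # -- reductions / shape ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def factory(out):
            def backward():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape))
            return backward

        return Tensor._result(data, (a,), factory)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        if axis is None:
            count = a.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([a.data.shape[ax] for ax in axes]))
        data = a.data.mean(axis=axis, keepdims=keepdims)

        def factory(out):
            def backward():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.data.shape) / count)
            return backward

        return Tensor._result(data, (a,), factory)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def factory(out):
            def backward():
                a._accumulate(out.grad.reshape(old))
            return backward

        return Tensor._result(a.data.reshape(*shape), (a,), factory)

    def transpose(self, *axes):
        a = self
        inverse = tuple(np.argsort(axes))

        def factory(out):
            def backward():
                a._accumulate(out.grad.transpose(inverse))
            return backward

        return Tensor._result(np.ascontiguousarray(a.data.transpose(axes)), (a,), factory)


# -- structural / convolutional primitives (channels-last layout) --------------------


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def factory(out):
        def backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])
        return backward

    return Tensor._result(data, tensors, factory)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) via im2col.

    ``x``: (N, H, W, Cin) channels-last; ``weight``: (Cout, Cin, kh, kw);
    ``bias``: (Cout,). ``pad=1`` with 3x3 kernels preserves the spatial size.
    """
    n, h, w, cin = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x.data
    ho, wo = xp.shape[1] - kh + 1, xp.shape[2] - kw + 1
    if kh == 1 and kw == 1:
        cols = xp.reshape(-1, cin)
    else:
        view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        cols = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, kh * kw * cin
        )
    # weight rearranged to match the (kh, kw, cin) column order
    wmat = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0)).reshape(
        kh * kw * cin, cout
    )
    out_mat = cols @ wmat
    if bias is not None:
        out_mat += bias.data
    data = out_mat.reshape(n, ho, wo, cout)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def factory(out):
        def backward():
            go = out.grad.reshape(-1, cout)
            if weight.requires_grad:
                dw = (cols.T @ go).reshape(kh, kw, cin, cout).transpose(3, 2, 0, 1)
                weight._accumulate(dw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(go.sum(axis=0))
            if x.requires_grad:
                dcols = (go @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
                dxp = np.zeros_like(xp)
                for a in range(kh):
                    for b in range(kw):
                        dxp[:, a:a + ho, b:b + wo, :] += dcols[:, :, :, a, b, :]
                x._accumulate(dxp[:, pad:pad + h, pad:pad + w, :] if pad else dxp)
        return backward

    return Tensor._result(data, parents, factory)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x2, stride-2 transposed convolution (exact 2x upsampling).

    ``x``: (N, H, W, Cin) channels-last; ``weight``: (Cin, Cout, 2, 2);
    output (N, 2H, 2W, Cout). Stride equals kernel size, so output blocks do
    not overlap.
    """
    n, h, w, cin = x.data.shape
    cin_w, cout = weight.data.shape[:2]
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    xm = x.data.reshape(-1, cin)
    wm = np.ascontiguousarray(weight.data.transpose(0, 2, 3, 1)).reshape(cin, 4 * cout)
    ym = xm @ wm
    data = np.ascontiguousarray(
        ym.reshape(n, h, w, 2, 2, cout).transpose(0, 1, 3, 2, 4, 5)
    ).reshape(n, 2 * h, 2 * w, cout)
    if bias is not None:
        data += bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def factory(out):
        def backward():
            gym = np.ascontiguousarray(
                out.grad.reshape(n, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
            ).reshape(-1, 4 * cout)
            if x.requires_grad:
                x._accumulate((gym @ wm.T).reshape(n, h, w, cin))
            if weight.requires_grad:
                dw = (xm.T @ gym).reshape(cin, 2, 2, cout).transpose(0, 3, 1, 2)
                weight._accumulate(dw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(out.grad.sum(axis=(0, 1, 2)))
        return backward

    return Tensor._result(data, parents, factory)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 on (N, H, W, C); H, W must be even."""
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    windows = np.ascontiguousarray(
        x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    ).reshape(n, h // 2, w // 2, c, 4)
    idx = windows.argmax(axis=-1)
    data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def factory(out):
        def backward():
            gwin = np.zeros_like(windows)
            np.put_along_axis(gwin, idx[..., None], out.grad[..., None], axis=-1)
            g = np.ascontiguousarray(
                gwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
            ).reshape(n, h, w, c)
            x._accumulate(g)
        return backward

    return Tensor._result(data, (x,), factory)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused instance normalization on (N, H, W, C) with affine transform.

    Normalizes each (sample, channel) slice over its spatial extent using the
    biased variance. Identical in training and evaluation (no running
    statistics). The backward pass uses the closed-form layer-norm gradient.
    """
    xd = x.data
    n, h, w, c = xd.shape
    m = h * w
    mu = xd.mean(axis=(1, 2), keepdims=True)
    xc = xd - mu
    var = np.einsum("nhwc,nhwc->nc", xc, xc).reshape(n, 1, 1, c) / m
    inv = 1.0 / np.sqrt(var + xd.dtype.type(eps))
    xhat = xc * inv
    data = xhat * gamma.data + beta.data

    def factory(out):
        def backward():
            go = out.grad
            if gamma.requires_grad:
                gamma._accumulate(np.einsum("nhwc,nhwc->c", go, xhat))
            if beta.requires_grad:
                beta._accumulate(go.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                dxhat = go * gamma.data
                s1 = dxhat.mean(axis=(1, 2), keepdims=True)
                s2 = np.einsum("nhwc,nhwc->nc", dxhat, xhat).reshape(n, 1, 1, c) / m
                x._accumulate(inv * (dxhat - s1 - xhat * s2))
        return backward

    return Tensor._result(data, (x, gamma, beta), factory)


def spatial_max(x: Tensor) -> Tensor:
    """Max over the spatial dimensions of (N, C, H, W) -> (N, C)."""
    n, c = x.data.shape[:2]
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=-1)
    data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def factory(out):
        def backward():
            g = np.zeros_like(flat)
            np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
            x._accumulate(g.reshape(x.data.shape))
        return backward

    return Tensor._result(data, (x,), factory)
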