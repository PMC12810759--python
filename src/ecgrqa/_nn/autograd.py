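"""Reverse-mode automatic differentiation over numpy arrays."""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Iterable["Tensor"] = ()):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: Tuple[Tensor, ...] = tuple(_prev)

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._prev:  # intermediate: its gradient is no longer needed
                t.grad = None

    # -- elementwise arithmetic --------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / other.data**2, other.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data**(p - 1))
        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        out._backward = bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self):
        out = Tensor(self.data.sum(), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g))
        out._backward = bw
        return out

    def mean(self):
        out = Tensor(self.data.mean(), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data,
                                         g / self.data.size))
        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    __matmul__ = matmul


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce *grad* back to *shape* after numpy broadcasting."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- convolution primitives (pure numpy) -----------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, s: int, p: int):
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    N, C, Ho, Wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    return np.ascontiguousarray(cols), Ho, Wo


def _conv2d_fwd(x, w, s, p):
    F, C, kh, kw = w.shape
    N = x.shape[0]
    cols, Ho, Wo = _im2col(x, kh, kw, s, p)
    y = cols @ w.reshape(F, -1).T
    return y.reshape(N, Ho, Wo, F).transpose(0, 3, 1, 2)


def _conv2d_dw(dy, x, w_shape, s, p):
    F, C, kh, kw = w_shape
    cols, Ho, Wo = _im2col(x, kh, kw, s, p)
    dy2 = dy.transpose(0, 2, 3, 1).reshape(-1, F)
    return (dy2.T @ cols).reshape(F, C, kh, kw)


def _conv2d_dx(dy, w, x_shape, s, p):
    N, C, H, W = x_shape
    F, _, kh, kw = w.shape
    Ho, Wo = dy.shape[2], dy.shape[3]
    dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dy.dtype)
    for i in range(kh):
        for j in range(kw):
            # (N,F,Ho,Wo) x (F,C) -> (N,Ho,Wo,C)
            contrib = np.tensordot(dy, w[:, :, i, j], axes=([1], [0]))
            dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                contrib.transpose(0, 3, 1, 2)
    if p:
        return dxp[:, :, p:p + H, p:p + W]
    return dxp


def conv2d(x: Tensor, w: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution; ``x`` (N,C,H,W), ``w`` (F,C,kh,kw)."""
    out_data = _conv2d_fwd(x.data, w.data, stride, padding)
    prev = [x, w]
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        prev.append(bias)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bw(g):
        if x.requires_grad:
            x._accum(_conv2d_dx(g, w.data, x.shape, stride, padding))
        if w.requires_grad:
            w._accum(_conv2d_dw(g, x.data, w.shape, stride, padding))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
    out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, bias: Optional[Tensor] = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed 2-D convolution (adjoint of :func:`conv2d`).

    ``x`` (N,Cin,H,W), ``w`` (Cin,Cout,kh,kw); output spatial side is
    (H-1)*stride - 2*padding + kh.
    """
    N, Cin, H, W = x.shape
    _, Cout, kh, kw = w.shape
    Hout = (H - 1) * stride - 2 * padding + kh
    Wout = (W - 1) * stride - 2 * padding + kw
    out_data = _conv2d_dx(x.data, w.data, (N, Cout, Hout, Wout),
                          stride, padding)
    prev = [x, w]
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        prev.append(bias)
    out = Tensor(out_data, any(t.requires_grad for t in prev), prev)

    def bw(g):
        if x.requires_grad:
            x._accum(_conv2d_fwd(g, w.data, stride, padding))
        if w.requires_grad:
            w._accum(_conv2d_dw(x.data, g, w.shape, stride, padding))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    z = logits.data
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(probs[np.arange(n), labels] + 1e-300).mean()
    out = Tensor(nll, logits.requires_grad, (logits,))

    def bw(g):
        if logits.requires_grad:
            gm = probs.copy()
            gm[np.arange(n), labels] -= 1.0
            logits._accum(g * gm / n)
    out._backward = bw
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
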