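"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: every operation builds a
:class:`Tensor` holding the forward value and a closure that accumulates
gradients into its inputs. Only the operations needed by the
encoder/classifier/decoder network and its objectives are provided
(dense and convolutional linear maps, element-wise nonlinearities,
reductions, softmax, concatenation).

Gradient correctness of every primitive is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from ._kernels import col2im as _col2im_impl
from ._kernels import im2col as _im2col_impl

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-dimensional array with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ------------------------------------------------------------------ basics
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, prev, backward) -> "Tensor":
        req = any(p.requires_grad for p in prev)
        out = Tensor(data, requires_grad=req, _prev=tuple(p for p in prev if p.requires_grad))
        if req:
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---------------------------------------------------------- nonlinearities
    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def clip_min(self, lo: float) -> "Tensor":
        """Element-wise maximum with a constant (straight-through below lo)."""
        mask = self.data >= lo

        def backward(g):
            self._accum(g * mask)

        return self._make(np.maximum(self.data, lo), (self,), backward)

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)

        def backward(g):
            self._accum(g * factor)

        return self._make(self.data * factor, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        return self._make(p, (self,), backward)

    # ----------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int, padding: int) -> "Tensor":
        """2-D cross-correlation; weight (Cout, Cin, kh, kw), input (N, Cin, H, W)."""
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        cout, cin, kh, kw = w.shape
        if cin != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
        cols, ho, wo = _im2col(x, kh, kw, stride, padding)
        wmat = w.reshape(cout, cin * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out_data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
            if weight.requires_grad:
                weight._accum((gmat.T @ cols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if self.requires_grad:
                dcols = gmat @ wmat
                self._accum(_col2im(dcols, (n, c, h, wd), kh, kw, stride, padding, ho, wo))

        prev = (self, weight) + (() if bias is None else (bias,))
        return self._make(out_data, prev, backward)

    def conv_transpose2d(
        self, weight: "Tensor", bias: "Tensor | None", stride: int, padding: int
    ) -> "Tensor":
        """Transposed convolution; weight (Cin, Cout, kh, kw), input (N, Cin, H, W)."""
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        cin, cout, kh, kw = w.shape
        if cin != c:
            raise ValueError(f"conv_transpose2d channel mismatch: input {c}, weight {cin}")
        ho = (h - 1) * stride - 2 * padding + kh
        wo = (wd - 1) * stride - 2 * padding + kw
        wmat = w.reshape(cin, cout * kh * kw)
        xmat = x.transpose(0, 2, 3, 1).reshape(-1, cin)
        cols = xmat @ wmat  # (N*H*W, Cout*kh*kw)
        out_data = _col2im(cols, (n, cout, ho, wo), kh, kw, stride, padding, h, wd)
        if bias is not None:
            out_data += bias.data[None, :, None, None]

        def backward(g):
            gcols, gh, gw = _im2col(g, kh, kw, stride, padding)
            if weight.requires_grad:
                weight._accum((xmat.T @ gcols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dx = (gcols @ wmat.T).reshape(n, gh, gw, cin).transpose(0, 3, 1, 2)
                self._accum(dx)

        prev = (self, weight) + (() if bias is None else (bias,))
        return self._make(out_data, prev, backward)

    # ---------------------------------------------------------------- engine
    def backward(self) -> None:
        """Run reverse-mode accumulation from this (scalar or any) tensor."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis, routing gradients back by slice."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, _prev=tuple(t for t in tensors if t.requires_grad))
    if req:
        out._backward = backward
    return out


# ---------------------------------------------------------------- im2col core
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """Unfold (N,C,H,W) into rows of receptive fields: (N*Ho*Wo, C*kh*kw)."""
    return _im2col_impl(x, kh, kw, stride, padding)


def _col2im(
    cols: np.ndarray,
    xshape: tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    padding: int,
    ho: int,
    wo: int,
) -> np.ndarray:
    """Scatter-add im2col rows back into an (N,C,H,W) array (adjoint of _im2col)."""
    return _col2im_impl(cols, xshape, kh, kw, stride, padding, ho, wo)
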