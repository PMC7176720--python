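"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Covers exactly the operations the U-Net variants need: 2-D convolution
(stride 1, 'same' padding), 2x2 transposed convolution with stride 2, 2x2
max-pooling, ReLU, channel concatenation and the elementwise arithmetic and
reductions used by the training loss.  Gradients flow through a recorded
tape; ``Tensor.backward()`` performs a topological sweep.

All computation is float64 for bit-reproducible training runs on any BLAS.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float64


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data - other.data, True, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(-g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, scalar: float) -> "Tensor":
        s = float(scalar)
        out = Tensor(self.data * s, True, (self,))
        out._backward = lambda g: self._accumulate(g * s)
        return out

    __rmul__ = __mul__

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), True, (self,))
        out._backward = lambda g: self._accumulate(g * sign)
        return out

    def square(self) -> "Tensor":
        out = Tensor(self.data ** 2, True, (self,))
        out._backward = lambda g: self._accumulate(g * 2.0 * self.data)
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), True, (self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape).astype(DTYPE))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), True, (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.data.shape).astype(DTYPE)
        )
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, True, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for stride-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k)
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1 'same' convolution; weight (F, C, k, k), bias (F,)."""
    n, c, h, w = x.data.shape
    f, c2, k, _ = weight.data.shape
    assert c == c2, f"channel mismatch {c} vs {c2}"
    pad = k // 2
    col = _im2col(x.data, k, pad)                       # (N, C*k*k, H*W)
    wmat = weight.data.reshape(f, c * k * k)
    y = np.einsum("fc,ncp->nfp", wmat, col, optimize=True).reshape(n, f, h, w)
    y += bias.data[None, :, None, None]
    out = Tensor(y, True, (x, weight, bias))
    flipped = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).copy()

    def bwd(g):
        gd = g.reshape(n, f, h * w)
        weight._accumulate(
            np.einsum("nfp,ncp->fc", gd, col, optimize=True).reshape(weight.data.shape)
        )
        bias._accumulate(g.sum(axis=(0, 2, 3)))
        # dx is the 'same' convolution of g with the flipped, transposed kernel
        gcol = _im2col(g, k, pad)
        fmat = flipped.reshape(c, f * k * k)
        x._accumulate(
            np.einsum("cf,nfp->ncp", fmat, gcol, optimize=True).reshape(n, c, h, w)
        )

    out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """2x upsampling transposed convolution, kernel 2, stride 2.

    weight (C_in, F, 2, 2); output spatial dims double.
    """
    n, c, h, w = x.data.shape
    c2, f, k, _ = weight.data.shape
    assert c == c2 and k == 2
    y6 = np.einsum("ncij,cfab->nfiajb", x.data, weight.data, optimize=True)
    y = y6.reshape(n, f, 2 * h, 2 * w) + bias.data[None, :, None, None]
    out = Tensor(y, True, (x, weight, bias))

    def bwd(g):
        g6 = g.reshape(n, f, h, 2, w, 2)
        x._accumulate(np.einsum("nfiajb,cfab->ncij", g6, weight.data, optimize=True))
        weight._accumulate(np.einsum("ncij,nfiajb->cfab", x.data, g6, optimize=True))
        bias._accumulate(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max-pooling, stride 2."""
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "spatial dims must be even"
    xr = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, True, (x,))

    def bwd(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        x._accumulate(
            gr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out
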