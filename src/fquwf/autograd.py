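"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine sized for the desk-scale convolutional networks in
this package: dense/strided/dilated 2-D convolution, transposed convolution,
the usual pointwise nonlinearities, reductions, reshapes and concatenation.
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the recorded graph.

Everything is float64 end to end; at the image sizes used here (tens of
pixels) exactness and reproducibility matter more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
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
    """A NumPy array plus a backward closure and parent links."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def _needs(self, *others) -> bool:
        return self.requires_grad or any(
            isinstance(o, Tensor) and o.requires_grad for o in others)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))
        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, self._needs(other), (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        out._backward = bwd
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by `pad` on every side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, width), self.requires_grad, (self,))
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def bwd(g):
            if self.requires_grad:
                self._accum(g[sl])
        out._backward = bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        out._backward = bwd
        return out

    def clamp(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad, (self,))
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        mask = self.data > 0.0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2):
        scale = np.where(self.data > 0.0, 1.0, slope)
        out = Tensor(self.data * scale, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * scale)
        out._backward = bwd
        return out

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))
        out._backward = bwd
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# im2col-based convolution primitives
# ---------------------------------------------------------------------------

def _out_size(H, W, kh, kw, stride, pad, dil):
    Hout = (H + 2 * pad - dil * (kh - 1) - 1) // stride + 1
    Wout = (W + 2 * pad - dil * (kw - 1) - 1) // stride + 1
    return Hout, Wout


def _im2col(x: np.ndarray, kh, kw, stride, pad, dil):
    """(N,C,H,W) -> (N, C*kh*kw, L) patch matrix (offset-sliced, no gather)."""
    N, C, H, W = x.shape
    Hout, Wout = _out_size(H, W, kh, kw, stride, pad, dil)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((N, C, kh * kw, Hout * Wout))
    for ki in range(kh):
        i0 = ki * dil
        for kj in range(kw):
            j0 = kj * dil
            patch = xp[:, :, i0:i0 + stride * (Hout - 1) + 1:stride,
                       j0:j0 + stride * (Wout - 1) + 1:stride]
            cols[:, :, ki * kw + kj, :] = patch.reshape(N, C, -1)
    return cols.reshape(N, C * kh * kw, -1), Hout, Wout


def _col2im(cols: np.ndarray, xshape, kh, kw, stride, pad, dil):
    """Slice-accumulating inverse of :func:`_im2col`."""
    N, C, H, W = xshape
    Hout, Wout = _out_size(H, W, kh, kw, stride, pad, dil)
    xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad))
    cols = cols.reshape(N, C, kh * kw, Hout, Wout)
    for ki in range(kh):
        i0 = ki * dil
        for kj in range(kw):
            j0 = kj * dil
            xp[:, :, i0:i0 + stride * (Hout - 1) + 1:stride,
               j0:j0 + stride * (Wout - 1) + 1:stride] += cols[:, :, ki * kw + kj]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, pad: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation. weight: (O, C, kh, kw); x: (N, C, H, W)."""
    O, C, kh, kw = weight.shape
    N = x.shape[0]
    cols, Hout, Wout = _im2col(x.data, kh, kw, stride, pad, dilation)
    W2 = weight.data.reshape(O, -1)
    out_data = np.matmul(W2, cols).reshape(N, O, Hout, Wout)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, O, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gf = g.reshape(N, O, -1)
        if weight.requires_grad:
            dW = np.tensordot(gf, cols, axes=([0, 2], [0, 2])).reshape(weight.shape)
            weight._accum(dW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(W2.T, gf)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, pad, dilation))
    out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
                     stride: int = 2, pad: int = 1, output_padding: int = 1) -> Tensor:
    """Transposed convolution. weight: (C_in, C_out, kh, kw); x: (N, C_in, H, W).

    Output spatial size: (H-1)*stride - 2*pad + kh + output_padding.
    """
    Ci, Co, kh, kw = weight.shape
    N, _, H, W = x.shape
    Hout = (H - 1) * stride - 2 * pad + kh + output_padding
    Wout = (W - 1) * stride - 2 * pad + kw + output_padding
    W2 = weight.data.reshape(Ci, -1)                 # (Ci, Co*kh*kw)
    xf = x.data.reshape(N, Ci, -1)                   # (N, Ci, H*W)
    cols = np.matmul(W2.T, xf)                       # (N, Co*kh*kw, H*W)
    out_data = _col2im(cols, (N, Co, Hout, Wout), kh, kw, stride, pad, 1)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, Co, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gcols, gH, gW = _im2col(g, kh, kw, stride, pad, 1)
        # patch grid of the gradient canvas must match the input grid
        gcols = gcols[:, :, : H * W]
        if weight.requires_grad:
            dW = np.tensordot(xf, gcols, axes=([0, 2], [0, 2])).reshape(weight.shape)
            weight._accum(dW)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.matmul(W2, gcols).reshape(x.shape)
            x._accum(dx)
    out._backward = bwd
    return out
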