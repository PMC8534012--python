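"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied
to it; :meth:`Tensor.backward` runs the chain rule through the recorded
graph in reverse topological order.  Gradients accumulate in ``.grad``.

Only float64 is used.  Broadcasting is supported for elementwise ops; the
gradient of a broadcast input is summed back to its original shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 expanded by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor.

        Seeds the output gradient with ones, which for the usual scalar
        loss is d(loss)/d(loss) = 1.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            if id(t) in seen:
                return
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- elementwise arithmetic -------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # -- matmul ------------------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        a, b = self.data, other.data
        out = Tensor(a @ b, _parents=(self, other))

        def bwd(g):
            # promote 1-D operands to matrices so one rule covers all cases
            aa = a[None, :] if a.ndim == 1 else a
            bb = b[:, None] if b.ndim == 1 else b
            gg = g
            if a.ndim == 1:
                gg = np.expand_dims(gg, -2)
            if b.ndim == 1:
                gg = np.expand_dims(gg, -1)
            if self.requires_grad:
                ga = _unbroadcast(gg @ np.swapaxes(bb, -1, -2), aa.shape)
                self._accumulate(ga.reshape(a.shape))
            if other.requires_grad:
                gb = _unbroadcast(np.swapaxes(aa, -1, -2) @ gg, bb.shape)
                other._accumulate(gb.reshape(b.shape))

        out._backward = bwd
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def sigmoid(self) -> "Tensor":
        s = _sigmoid(self.data)
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def relu(self) -> "Tensor":
        m = self.data > 0
        out = Tensor(self.data * m, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * m)
        return out

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- composite heads ---------------------------------------------------

    def log_softmax(self, axis: int = -1) -> "Tensor":
        x = self.data
        shifted = x - x.max(axis=axis, keepdims=True)
        logsum = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - logsum
        out = Tensor(ls, _parents=(self,))
        sm = np.exp(ls)

        def bwd(g):
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean multi-label binary cross-entropy on raw scores.

    Numerically stable: ``max(x,0) - x*t + log(1 + exp(-|x|))``; the
    gradient is ``(sigmoid(x) - t) / n``.
    """
    t = np.asarray(targets, dtype=np.float64)
    x = logits.data
    loss = np.maximum(x, 0.0) - x * t + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(np.array(loss.mean()), _parents=(logits,))

    def bwd(g):
        logits._accumulate(g * (_sigmoid(x) - t) / x.size)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolution and pooling (im2col based), as dedicated graph ops


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, H*W) patches with zero padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, h, w),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]),
        writeable=False,
    )
    return cols.reshape(n, c * kh * kw, h * w)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, pad: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add patches back into the image."""
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, c, kh, kw, h, w)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size 2-D convolution, stride 1, zero padding ``(k-1)//2``.

    ``x``: (N, C_in, H, W); ``w``: (C_out, C_in, kh, kw); ``b``: (C_out,).
    """
    n, cin, h, wdt = x.shape
    cout, cin2, kh, kw = w.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin2}")
    pad = (kh - 1) // 2
    cols = _im2col(x.data, kh, kw, pad)  # (N, C*kh*kw, H*W)
    wmat = w.data.reshape(cout, -1)
    out_data = np.einsum("ok,nkp->nop", wmat, cols) + b.data[None, :, None]
    out = Tensor(out_data.reshape(n, cout, h, wdt), _parents=(x, w, b))

    def bwd(g):
        gmat = g.reshape(n, cout, h * wdt)
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("nop,nkp->ok", gmat, cols)
            w._accumulate(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,nop->nkp", wmat, gmat)
            x._accumulate(_col2im(gcols, x.shape, kh, kw, pad))

    out._backward = bwd
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; H and W must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 needs even spatial dimensions")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = r.max(axis=(3, 5))
    # break ties toward the first maximal element in each 2x2 block
    blocks = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    first = np.zeros_like(blocks)
    idx = blocks.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], 1, axis=-1)
    mask = (
        first.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .astype(bool)
    )
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        gx = mask * g[:, :, :, None, :, None]
        x._accumulate(gx.reshape(n, c, h, w))

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    n, c, h, w = x.shape
    out = Tensor(
        np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,)
    )

    def bwd(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out
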