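"""Compact reverse-mode automatic differentiation over numpy arrays.

The package trains a volumetric segmentation network on CPU, so the engine
implements exactly the operator set that network needs: broadcast arithmetic,
batched matmul, softmax, sigmoid, PReLU, channel concatenation, zero padding,
axis sums, and three 3-D convolution variants (same-padded, strided
block-downsampling with kernel == stride, and the matching transpose
convolution).  Convolutions are evaluated as im2col matrix products, chunked
over the depth axis so a 36^3 grid never materialises a multi-GB column
matrix.  All arithmetic is float32.

Gradients flow through a dynamically built tape: every op records its parent
tensors and a closure that maps the output gradient to parent gradients;
``Tensor.backward`` runs the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32

# keep im2col slabs below ~32M floats (128 MB as float32)
_COL_BUDGET = 32_000_000

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_F32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or (
            _GRAD_ENABLED and any(p.requires_grad for p in parents)
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------- autodiff
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs would overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True) if g.dtype != _F32 else g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(-self, _wrap(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def sum(self, axis=None, keepdims: bool = False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self):
        return mul_scalar(tsum(self), 1.0 / self.data.size)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum `g` down to `shape` (reverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------- arithmetic
def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.shape))

    out._backward = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = bwd
    return out


def mul_scalar(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * _F32(s), parents=(a,))

    def bwd(g):
        a._accum(g * _F32(s))

    out._backward = bwd
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    out._backward = bwd
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape))

    out._backward = bwd
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def bwd(g):
        a._accum(g.reshape(a.shape))

    out._backward = bwd
    return out


def transpose(a: Tensor, axes) -> Tensor:
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)

    def bwd(g):
        a._accum(g.transpose(inv))

    out._backward = bwd
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    out._backward = bwd
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


def pad_spatial(a: Tensor, target_spatial) -> Tensor:
    """Zero-pad the three spatial axes of an (N, D, H, W, C) tensor at the end."""
    n, d, h, w, c = a.shape
    td, th, tw = target_spatial
    if (td, th, tw) == (d, h, w):
        return a
    pads = ((0, 0), (0, td - d), (0, th - h), (0, tw - w), (0, 0))
    out = Tensor(np.pad(a.data, pads), parents=(a,))

    def bwd(g):
        a._accum(g[:, :d, :h, :w, :])

    out._backward = bwd
    return out


# -------------------------------------------------------------- nonlinearities
def sigmoid(a: Tensor) -> Tensor:
    # numerically stable split by sign
    x = a.data
    s = np.empty_like(x)
    pos = x >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    s[~pos] = ex / (1.0 + ex)
    out = Tensor(s, parents=(a,))

    def bwd(g):
        a._accum(g * s * (1.0 - s))

    out._backward = bwd
    return out


def prelu(a: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with per-channel slope; channels on the last axis."""
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, alpha.data * a.data), parents=(a, alpha))

    def bwd(g):
        if a.requires_grad:
            a._accum(np.where(pos, g, alpha.data * g))
        if alpha.requires_grad:
            ga = np.where(pos, 0.0, g * a.data)
            alpha._accum(ga.reshape(-1, a.shape[-1]).sum(axis=0))

    out._backward = bwd
    return out


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(a,))

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    out._backward = bwd
    return out


# -------------------------------------------------------------- convolutions
def _conv_same_raw(xd: np.ndarray, wd: np.ndarray, bd: np.ndarray | None) -> np.ndarray:
    """Same-padded stride-1 conv, chunked over output depth."""
    n, d, h, w, ci = xd.shape
    k = wd.shape[0]
    co = wd.shape[-1]
    p = k // 2
    wr = wd.reshape(k * k * k * ci, co)
    xp = np.pad(xd, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    out = np.empty((n, d, h, w, co), dtype=_F32)
    slab = max(1, _COL_BUDGET // max(1, n * h * w * k * k * k * ci))
    for z0 in range(0, d, slab):
        z1 = min(d, z0 + slab)
        v = np.lib.stride_tricks.sliding_window_view(
            xp[:, z0 : z1 + 2 * p], (k, k, k), axis=(1, 2, 3)
        )  # (n, z1-z0, h, w, ci, k, k, k)
        cols = v.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(n, z1 - z0, h, w, -1)
        out[:, z0:z1] = cols @ wr
    if bd is not None:
        out += bd
    return out


def conv3d_same(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """3-D convolution, odd kernel, stride 1, zero 'same' padding.

    x: (N, D, H, W, Cin); w: (k, k, k, Cin, Cout); b: (Cout,) or None.
    """
    out = Tensor(
        _conv_same_raw(x.data, w.data, None if b is None else b.data),
        parents=(x, w) if b is None else (x, w, b),
    )
    k = w.data.shape[0]
    p = k // 2

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2, 3)))
        if x.requires_grad:
            wflip = w.data[::-1, ::-1, ::-1].transpose(0, 1, 2, 4, 3)
            x._accum(_conv_same_raw(g, np.ascontiguousarray(wflip), None))
        if w.requires_grad:
            n, d, h, wid, ci = x.shape
            co = g.shape[-1]
            xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
            gw = np.zeros((k * k * k * ci, co), dtype=_F32)
            slab = max(1, _COL_BUDGET // max(1, n * h * wid * k * k * k * ci))
            for z0 in range(0, d, slab):
                z1 = min(d, z0 + slab)
                v = np.lib.stride_tricks.sliding_window_view(
                    xp[:, z0 : z1 + 2 * p], (k, k, k), axis=(1, 2, 3)
                )
                cols = v.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(-1, k * k * k * ci)
                gw += cols.T @ g[:, z0:z1].reshape(-1, co)
            w._accum(gw.reshape(w.shape))

    out._backward = bwd
    return out


def conv3d_down(x: Tensor, w: Tensor, b: Tensor | None, factors=(2, 2, 2)) -> Tensor:
    """Strided downsampling conv with kernel == stride (no overlap, no padding).

    Odd spatial dims are floored: trailing rows that do not fill a block are
    dropped, matching a valid-mode strided convolution.
    w: (fz, fy, fx, Cin, Cout).
    """
    fz, fy, fx = factors
    n, d, h, wid, ci = x.shape
    do, ho, wo = d // fz, h // fy, wid // fx
    xc = x.data[:, : do * fz, : ho * fy, : wo * fx, :]
    blocks = xc.reshape(n, do, fz, ho, fy, wo, fx, ci).transpose(0, 1, 3, 5, 2, 4, 6, 7)
    cols = blocks.reshape(n, do, ho, wo, fz * fy * fx * ci)
    wr = w.data.reshape(fz * fy * fx * ci, -1)
    y = cols @ wr
    if b is not None:
        y = y + b.data
    out = Tensor(y, parents=(x, w) if b is None else (x, w, b))

    def bwd(g):
        co = g.shape[-1]
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2, 3)))
        if w.requires_grad:
            gw = cols.reshape(-1, cols.shape[-1]).T @ g.reshape(-1, co)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = g @ wr.T  # (n, do, ho, wo, f^3*ci)
            gblocks = gcols.reshape(n, do, ho, wo, fz, fy, fx, ci).transpose(
                0, 1, 4, 2, 5, 3, 6, 7
            )
            gx = np.zeros_like(x.data)
            gx[:, : do * fz, : ho * fy, : wo * fx, :] = gblocks.reshape(
                n, do * fz, ho * fy, wo * fx, ci
            )
            x._accum(gx)

    out._backward = bwd
    return out


def conv3d_up(x: Tensor, w: Tensor, b: Tensor | None, factors=(2, 2, 2)) -> Tensor:
    """Transpose convolution with kernel == stride (block upsampling).

    w: (fz, fy, fx, Cin, Cout); output spatial dims are input dims * factors.
    """
    fz, fy, fx = factors
    n, d, h, wid, ci = x.shape
    co = w.shape[-1]
    wr = w.data.transpose(3, 0, 1, 2, 4).reshape(ci, fz * fy * fx * co)
    ycols = x.data @ wr  # (n, d, h, w, f^3*co)
    y = (
        ycols.reshape(n, d, h, wid, fz, fy, fx, co)
        .transpose(0, 1, 4, 2, 5, 3, 6, 7)
        .reshape(n, d * fz, h * fy, wid * fx, co)
    )
    if b is not None:
        y = y + b.data
    out = Tensor(y, parents=(x, w) if b is None else (x, w, b))

    def bwd(g):
        gcols = (
            g.reshape(n, d, fz, h, fy, wid, fx, co)
            .transpose(0, 1, 3, 5, 2, 4, 6, 7)
            .reshape(n, d, h, wid, fz * fy * fx * co)
        )
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2, 3)))
        if w.requires_grad:
            gw = x.data.reshape(-1, ci).T @ gcols.reshape(-1, gcols.shape[-1])
            w._accum(gw.reshape(ci, fz, fy, fx, co).transpose(1, 2, 3, 0, 4))
        if x.requires_grad:
            x._accum(gcols @ wr.T)

    out._backward = bwd
    return out
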