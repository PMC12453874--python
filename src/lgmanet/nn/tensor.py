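"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each operation returns a new :class:`Tensor`
holding the forward value and a closure that accumulates gradients into its
parents. Arrays are kept in float32; convolutions run through im2col and a
single BLAS matmul, which is where essentially all the training time goes.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE, copy=False)
    return np.asarray(x, dtype=_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing ------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True) if g.base is not None or g.dtype != _DTYPE else g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Back-propagate from this node (default seed: ones)."""
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
        self.grad = _as_array(grad).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, 1.0 / float(other))
        return mul(self, reciprocal(other))

    def __rtruediv__(self, other):
        return mul_scalar(reciprocal(self), float(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward, requires):
    out = Tensor(data, requires_grad=requires)
    if requires:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


# ---------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw, req)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw, req)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def bw(g):
        a._accumulate(g * s)

    return _make(a.data * _DTYPE(s), (a,), bw, a.requires_grad)


def reciprocal(a: Tensor) -> Tensor:
    out_data = 1.0 / a.data

    def bw(g):
        a._accumulate(-g * out_data * out_data)

    return _make(out_data, (a,), bw, a.requires_grad)


def power(a: Tensor, p: float) -> Tensor:
    def bw(g):
        a._accumulate(g * p * np.power(a.data, p - 1))

    return _make(np.power(a.data, p), (a,), bw, a.requires_grad)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims, dtype=_DTYPE), (a,), bw, a.requires_grad)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))])
    return mul_scalar(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def bw(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bw, a.requires_grad)


def transpose(a: Tensor, axes=None) -> Tensor:
    def bw(g):
        inv = np.argsort(axes) if axes is not None else None
        a._accumulate(g.transpose(inv) if inv is not None else g.transpose())

    return _make(a.data.transpose(axes), (a,), bw, a.requires_grad)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw, req)


def pad2d(a: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int]) -> Tensor:
    """Zero-pad the last two axes of a rank-4 tensor."""
    def bw(g):
        h0, h1 = pad_h
        w0, w1 = pad_w
        H = a.data.shape[2]
        W = a.data.shape[3]
        a._accumulate(g[:, :, h0:h0 + H, w0:w0 + W])

    data = np.pad(a.data, ((0, 0), (0, 0), pad_h, pad_w))
    return _make(data, (a,), bw, a.requires_grad)


def slice2d(a: Tensor, hs: slice, ws: slice) -> Tensor:
    """Slice the last two axes of a rank-4 tensor."""
    def bw(g):
        buf = np.zeros_like(a.data)
        buf[:, :, hs, ws] = g
        a._accumulate(buf)

    return _make(a.data[:, :, hs, ws], (a,), bw, a.requires_grad)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    req = a.requires_grad or b.requires_grad

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(a.data @ b.data, (a, b), bw, req)


# ---------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    out_data = _sp.expit(a.data).astype(_DTYPE)

    def bw(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw, a.requires_grad)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return _make(np.where(mask, a.data, 0), (a,), bw, a.requires_grad)


def gelu(a: Tensor) -> Tensor:
    """Exact GELU: x * Phi(x)."""
    x = a.data
    cdf = 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0, dtype=_DTYPE)))

    def bw(g):
        pdf = np.exp(-0.5 * x * x) / _DTYPE(np.sqrt(2.0 * np.pi))
        a._accumulate(g * (cdf + x * pdf))

    return _make(x * cdf, (a,), bw, a.requires_grad)


def prelu(a: Tensor, alpha: Tensor) -> Tensor:
    """Channelwise PReLU on a (B,C,H,W) tensor; alpha has shape (C,)."""
    x = a.data
    al = alpha.data.reshape(1, -1, 1, 1)
    pos = x > 0
    neg = ~pos
    req = a.requires_grad or alpha.requires_grad

    def bw(g):
        if a.requires_grad:
            a._accumulate(g * np.where(pos, 1.0, al).astype(_DTYPE))
        if alpha.requires_grad:
            alpha._accumulate((g * np.where(neg, x, 0)).sum(axis=(0, 2, 3), dtype=_DTYPE))

    return _make(np.where(pos, x, al * x), (a, alpha), bw, req)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller decides (via module mode) whether to apply."""
    if rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep).astype(_DTYPE) / _DTYPE(keep)

    def bw(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw, a.requires_grad)


# ---------------------------------------------------------------------
# structured primitives: convolution, pooling, resampling, normalisation
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*kh*kw, Ho*Wo), stride/pad symmetric."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
    return cols.reshape(B, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad):
    B, C, H, W = xshape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    dxp = np.zeros((B, C, Hp, Wp), dtype=dcols.dtype)
    d6 = dcols.reshape(B, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad:pad + H, pad:pad + W]
    return dxp


def _conv2d_strided(x: Tensor, weight: Tensor, bias, stride: int, padding: int) -> Tensor:
    """im2col path, used for stride > 1 (patch-merging convolutions)."""
    Cout, Cin, kh, kw = weight.data.shape
    cols, Ho, Wo = _im2col(x.data, kh, kw, stride, padding)
    Wm = weight.data.reshape(Cout, Cin * kh * kw)
    B = x.data.shape[0]
    out = np.matmul(Wm, cols).reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out += bias.data.reshape(1, Cout, 1, 1)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def bw(g):
        gf = np.ascontiguousarray(g.reshape(B, Cout, Ho * Wo))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2), dtype=_DTYPE))
        if weight.requires_grad:
            dW = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dW.reshape(weight.data.shape))
        if x.requires_grad:
            dcols = np.matmul(Wm.T, gf)
            x._accumulate(_col2im(dcols, x.data.shape, kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw, req)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int | None = None) -> Tensor:
    """2-D cross-correlation. weight: (Cout, Cin, kh, kw); padding defaults
    to "same" (kh//2).

    The stride-1 path runs one BLAS matmul per kernel offset against the
    padded input, accumulating shifted views; this avoids materialising
    im2col column matrices, which at training batch sizes would dominate
    both memory and bandwidth.
    """
    Cout, Cin, kh, kw = weight.data.shape
    if x.data.shape[1] != Cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]} channels, "
            f"weight expects {Cin}")
    if padding is None:
        padding = kh // 2
    if stride != 1:
        return _conv2d_strided(x, weight, bias, stride, padding)

    B, _, H, W = x.data.shape
    p = padding
    Hp, Wp = H + 2 * p, W + 2 * p
    Ho, Wo = Hp - kh + 1, Wp - kw + 1
    if p:
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = x.data
    xpf = xp.reshape(B, Cin, Hp * Wp)
    Wk = weight.data
    out = np.zeros((B, Cout, Ho, Wo), dtype=_DTYPE)
    tmp = np.empty((B, Cout, Hp * Wp), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            np.matmul(Wk[:, :, i, j], xpf, out=tmp)
            out += tmp.reshape(B, Cout, Hp, Wp)[:, :, i:i + Ho, j:j + Wo]
    if bias is not None:
        out += bias.data.reshape(1, Cout, 1, 1)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)
    if not req:
        return _make(out, (), None, False)

    def bw(g):
        gf = np.ascontiguousarray(g.reshape(B, Cout, Ho * Wo))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2), dtype=_DTYPE))
        if weight.requires_grad:
            dW = np.empty_like(Wk)
            buf = np.empty((B, Cin, Ho, Wo), dtype=_DTYPE)
            for i in range(kh):
                for j in range(kw):
                    np.copyto(buf, xp[:, :, i:i + Ho, j:j + Wo])
                    bf = buf.reshape(B, Cin, Ho * Wo)
                    dW[:, :, i, j] = np.matmul(gf, bf.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(dW)
        if x.requires_grad:
            dxp = np.zeros((B, Cin, Hp, Wp), dtype=_DTYPE)
            dtmp = np.empty((B, Cin, Ho * Wo), dtype=_DTYPE)
            for i in range(kh):
                for j in range(kw):
                    np.matmul(Wk[:, :, i, j].T, gf, out=dtmp)
                    dxp[:, :, i:i + Ho, j:j + Wo] += dtmp.reshape(B, Cin, Ho, Wo)
            x._accumulate(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw, req)


def depthwise_conv3x3(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Depthwise 3x3, stride 1, same padding. weight: (C,1,3,3)."""
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    w = weight.data.reshape(C, 3, 3)
    out = np.zeros((B, C, H, W), dtype=_DTYPE)
    for i in range(3):
        for j in range(3):
            out += xp[:, :, i:i + H, j:j + W] * w[:, i, j].reshape(1, C, 1, 1)
    if bias is not None:
        out += bias.data.reshape(1, C, 1, 1)
    req = x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad)

    def bw(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3), dtype=_DTYPE))
        if weight.requires_grad:
            dw = np.empty((C, 3, 3), dtype=_DTYPE)
            for i in range(3):
                for j in range(3):
                    dw[:, i, j] = (g * xp[:, :, i:i + H, j:j + W]).sum(axis=(0, 2, 3), dtype=_DTYPE)
            weight._accumulate(dw.reshape(weight.data.shape))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    dxp[:, :, i:i + H, j:j + W] += g * w[:, i, j].reshape(1, C, 1, 1)
            x._accumulate(dxp[:, :, 1:1 + H, 1:1 + W])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, bw, req)


def conv1d_channel(desc: Tensor, weight: Tensor) -> Tensor:
    """Bias-free 1-D convolution over the channel axis of a (B, C) descriptor.

    weight has shape (k,), k odd; zero padding k//2 keeps length C. This is
    the adaptive-kernel channel-interaction convolution of ECA-style
    attention.
    """
    k = weight.data.shape[0]
    p = k // 2
    B, C = desc.data.shape
    xp = np.pad(desc.data, ((0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, C, k)
    out = win @ weight.data
    req = desc.requires_grad or weight.requires_grad

    def bw(g):
        if weight.requires_grad:
            weight._accumulate(np.tensordot(g, win, axes=([0, 1], [0, 1])))
        if desc.requires_grad:
            gp = np.pad(g, ((0, 0), (p, p)))
            gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=1)
            desc._accumulate(gwin @ weight.data[::-1].copy())

    return _make(out, (desc, weight), bw, req)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C) spatial mean."""
    B, C, H, W = x.data.shape
    n = H * W

    def bw(g):
        x._accumulate(np.broadcast_to((g / _DTYPE(n))[:, :, None, None], x.data.shape).copy())

    return _make(x.data.mean(axis=(2, 3), dtype=_DTYPE), (x,), bw, x.requires_grad)


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    Ho, Wo = H // 2, W // 2
    xr = x.data.reshape(B, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        buf = np.zeros((B, C, Ho, Wo, 4), dtype=_DTYPE)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        dx = buf.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
        x._accumulate(dx)

    return _make(out, (x,), bw, x.requires_grad)


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    # bilinear x2, half-pixel centres: even outputs 0.25*x[m-1]+0.75*x[m],
    # odd outputs 0.75*x[m]+0.25*x[m+1], clamped at the borders.
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.25 * prev + 0.75 * x
    out[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _down2_axis(g: np.ndarray, axis: int) -> np.ndarray:
    # adjoint of _up2_axis
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    dx = 0.75 * ge + 0.75 * go
    # shifted contributions
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, axis)


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling of a (B,C,H,W) tensor (half-pixel centres)."""
    out = _up2_axis(_up2_axis(x.data, 2), 3)

    def bw(g):
        x._accumulate(_down2_axis(_down2_axis(g, 3), 2).astype(_DTYPE))

    return _make(out, (x,), bw, x.requires_grad)


def _shift_zero(arr: np.ndarray, s: int, axis: int) -> np.ndarray:
    """Shift along `axis` by `s` with zero fill (positive s moves content forward)."""
    if s == 0:
        return arr
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    if s > 0:
        dst[axis] = slice(s, None)
        src[axis] = slice(None, -s)
    else:
        dst[axis] = slice(None, s)
        src[axis] = slice(-s, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def axial_shift(x: Tensor, shift_size: int, axis: int) -> Tensor:
    """Partition channels into `shift_size` groups and shift group g by
    g - shift_size//2 pixels along the given spatial axis, zero-filling the
    vacated border. The adjoint is the same operation with negated shifts."""
    B, C, H, W = x.data.shape
    bounds = np.array_split(np.arange(C), shift_size)
    offsets = [g - shift_size // 2 for g in range(shift_size)]

    def apply(arr, sign):
        out = np.empty_like(arr)
        for idx, off in zip(bounds, offsets):
            if len(idx) == 0:
                continue
            sl = slice(idx[0], idx[-1] + 1)
            out[:, sl] = _shift_zero(arr[:, sl], sign * off, axis)
        return out

    def bw(g):
        x._accumulate(apply(g, -1))

    return _make(apply(x.data, +1), (x,), bw, x.requires_grad)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """BatchNorm over (B,H,W) per channel; updates running stats in place."""
    B, C, H, W = x.data.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3), dtype=_DTYPE)
        var = x.data.var(axis=(0, 2, 3), dtype=_DTYPE)
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps, dtype=_DTYPE)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) / std.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    n = B * H * W

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3), dtype=_DTYPE))
        dgamma = (g * xhat).sum(axis=(0, 2, 3), dtype=_DTYPE)
        if gamma.requires_grad:
            gamma._accumulate(dgamma)
        if x.requires_grad:
            gsum = g.sum(axis=(0, 2, 3), dtype=_DTYPE)
            if training:
                dx = (gamma.data / (n * std)).reshape(1, C, 1, 1) * (
                    n * g - gsum.reshape(1, C, 1, 1) - xhat * dgamma.reshape(1, C, 1, 1))
            else:
                dx = (gamma.data / std).reshape(1, C, 1, 1) * g
            x._accumulate(dx.astype(_DTYPE))

    return _make(out, (x, gamma, beta), bw, req)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """LayerNorm over the last axis (token features)."""
    mu = x.data.mean(axis=-1, keepdims=True, dtype=_DTYPE)
    var = x.data.var(axis=-1, keepdims=True, dtype=_DTYPE)
    std = np.sqrt(var + eps, dtype=_DTYPE)
    xhat = (x.data - mu) / std
    out = gamma.data * xhat + beta.data
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    n = x.data.shape[-1]
    red = tuple(range(x.data.ndim - 1))

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red, dtype=_DTYPE))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=red, dtype=_DTYPE))
        if x.requires_grad:
            gh = g * gamma.data
            dx = (gh - gh.mean(axis=-1, keepdims=True)
                  - xhat * (gh * xhat).mean(axis=-1, keepdims=True)) / std
            x._accumulate(dx.astype(_DTYPE))

    return _make(out, (x, gamma, beta), bw, req)
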