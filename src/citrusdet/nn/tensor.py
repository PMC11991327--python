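"""Minimal reverse-mode autodiff over NumPy arrays.

Supports exactly the operations the detector needs: grouped/dilated 2-D
convolution (im2col), batch norm, SiLU/sigmoid/softmax, max-pooling,
nearest-neighbour upsampling, concatenation/chunking and elementwise
arithmetic.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.float64 if self.data.dtype == np.float64 else np.float32)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    # ------------------------------------------------------------- primitives
    def _unary(self, out_data, bwd):
        out = Tensor(out_data, requires_grad=self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)

            def _b():
                self._accum(bwd(out.grad))

            out._backward = _b
        return out

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _b():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad, other.data.shape))

            out._backward = _b
        return out

    __radd__ = __add__

    def __neg__(self):
        return self._unary(-self.data, lambda g: -g)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _b():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

            out._backward = _b
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._prev = (self, other)

            def _b():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-out.grad * self.data / other.data ** 2, other.data.shape))

            out._backward = _b
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            out._prev = (self,)

            def _b():
                g = np.zeros_like(self.data, dtype=out.grad.dtype)
                np.add.at(g, idx, out.grad)
                self._accum(g)

            out._backward = _b
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return self._unary(self.data.reshape(shape), lambda g: g.reshape(old))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._unary(self.data.transpose(axes), lambda g: g.transpose(inv))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return self._unary(out_data, bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def clamp_min(self, lo):
        mask = self.data >= lo
        return self._unary(np.maximum(self.data, lo), lambda g: g * mask)

    def exp(self):
        e = np.exp(self.data)
        return self._unary(e, lambda g: g * e)

    def log(self):
        return self._unary(np.log(self.data), lambda g: g / self.data)

    def sigmoid(self):
        s = _sigmoid(self.data)
        return self._unary(s, lambda g: g * s * (1.0 - s))

    def silu(self):
        s = _sigmoid(self.data)
        y = self.data * s
        return self._unary(y, lambda g: g * (s + y * (1.0 - s)))

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            return p * (g - (g * p).sum(axis=axis, keepdims=True))

        return self._unary(p, bwd)

    def sqrt(self):
        r = np.sqrt(self.data)
        return self._unary(r, lambda g: g * 0.5 / r)

    def abs(self):
        s = np.sign(self.data)
        return self._unary(np.abs(self.data), lambda g: g * s)

    def arctan(self):
        return self._unary(np.arctan(self.data), lambda g: g / (1.0 + self.data ** 2))

    def maximum(self, other):
        other = as_tensor(other)
        out = Tensor(np.maximum(self.data, other.data), self.requires_grad or other.requires_grad)
        if out.requires_grad:
            m = self.data >= other.data
            out._prev = (self, other)

            def _b():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * m, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * (~m), other.data.shape))

            out._backward = _b
        return out

    def minimum(self, other):
        other = as_tensor(other)
        out = Tensor(np.minimum(self.data, other.data), self.requires_grad or other.requires_grad)
        if out.requires_grad:
            m = self.data <= other.data
            out._prev = (self, other)

            def _b():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * m, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * (~m), other.data.shape))

            out._backward = _b
        return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------- conv
def _im2col(x, kh, kw, stride, dilation):
    """x: (B,C,H,W) padded.  Returns view (B, C, kh, kw, Ho, Wo)."""
    B, C, H, W = x.shape
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    Ho = (H - eh) // stride + 1
    Wo = (W - ew) // stride + 1
    sB, sC, sH, sW = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, kh, kw, Ho, Wo),
        strides=(sB, sC, sH * dilation, sW * dilation, sH * stride, sW * stride),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0, dilation=1, groups=1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (Co, Ci/groups, kh, kw).
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    Co, Cg, kh, kw = wd.shape
    G = groups
    assert C == Cg * G, f"channel mismatch: {C} vs {Cg}x{G}"
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    cols = _im2col(xp, kh, kw, stride, dilation)          # (B,C,kh,kw,Ho,Wo)
    Ho, Wo = cols.shape[4], cols.shape[5]
    cols_g = cols.reshape(B, G, Cg, kh * kw, Ho * Wo)
    w_g = wd.reshape(G, Co // G, Cg * kh * kw)
    out = np.einsum("gof,bgfp->bgop", w_g, cols_g.reshape(B, G, Cg * kh * kw, Ho * Wo), optimize=True)
    out = out.reshape(B, Co, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1)

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    res = Tensor(out, requires_grad=req)
    if not res.requires_grad:
        return res
    prev = [t for t in (x, w, b) if t is not None]
    res._prev = tuple(prev)

    def _b():
        g = res.grad  # (B,Co,Ho,Wo)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bgop,bgfp->gof", g.reshape(B, G, Co // G, Ho * Wo),
                           cols_g.reshape(B, G, Cg * kh * kw, Ho * Wo), optimize=True)
            w._accum(gw.reshape(wd.shape))
        if x.requires_grad:
            gx = np.zeros_like(xp, dtype=g.dtype)
            g_g = g.reshape(B, G, Co // G, Ho, Wo)
            w_r = wd.reshape(G, Co // G, Cg, kh, kw)
            # accumulate per kernel tap
            gcol = np.einsum("bgohw,gocij->bgcijhw", g_g, w_r, optimize=True)
            gcol = gcol.reshape(B, C, kh, kw, Ho, Wo)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gx[:, :, hi:hi + Ho * stride:stride, wj:wj + Wo * stride:stride] += gcol[:, :, i, j]
            if padding:
                gx = gx[:, :, padding:-padding or None, padding:-padding or None]
            x._accum(gx)

    res._backward = _b
    return res


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    xd = x.data
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = xd
    cols = _im2col(xp, k, k, stride, 1)  # (B,C,k,k,Ho,Wo)
    B, C, _, _, Ho, Wo = cols.shape
    flat = cols.reshape(B, C, k * k, Ho, Wo)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
    res = Tensor(out, requires_grad=x.requires_grad)
    if res.requires_grad:
        res._prev = (x,)

        def _b():
            g = res.grad
            gx = np.zeros_like(xp, dtype=g.dtype)
            ki, kj = np.divmod(idx, k)  # (B,C,Ho,Wo)
            bb, cc, hh, ww = np.meshgrid(np.arange(B), np.arange(C), np.arange(Ho), np.arange(Wo), indexing="ij")
            np.add.at(gx, (bb, cc, hh * stride + ki, ww * stride + kj), g)
            if padding:
                gx = gx[:, :, padding:-padding or None, padding:-padding or None]
            x._accum(gx)

        res._backward = _b
    return res


def upsample_nearest2(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    res = Tensor(out, requires_grad=x.requires_grad)
    if res.requires_grad:
        res._prev = (x,)
        B, C, H, W = x.data.shape

        def _b():
            g = res.grad.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))
            x._accum(g)

        res._backward = _b
    return res


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._prev = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]

        def _b():
            splits = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
            for t, g in zip(tensors, splits):
                if t.requires_grad:
                    t._accum(g)

        out._backward = _b
    return out


def chunk(x: Tensor, n: int, axis=1):
    """Split into ``n`` equal parts along ``axis``."""
    size = x.data.shape[axis]
    assert size % n == 0, f"cannot chunk axis of size {size} into {n}"
    step = size // n
    outs = []
    for i in range(n):
        sl = [slice(None)] * x.data.ndim
        sl[axis] = slice(i * step, (i + 1) * step)
        outs.append(x[tuple(sl)])
    return outs
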