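"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations needed by the segmentation network are provided: broadcasted
arithmetic, pointwise nonlinearities, reductions, concatenation, 3D convolution
(im2col + BLAS matmul), factor-2 trilinear upsampling (align_corners=False) and
factor-2 mean-pool downsampling. Everything is float64 so results can be compared
against scalar-loop oracles at tight tolerances.
"""

from __future__ import annotations

import contextlib

import numpy as np

_DTYPE = np.dtype(np.float64)


def dtype() -> np.dtype:
    """Current compute dtype (float64 by default for oracle-tight precision)."""
    return _DTYPE


@contextlib.contextmanager
def use_dtype(dt):
    """Temporarily switch the compute dtype (float32 speeds up training ~2x)."""
    global _DTYPE
    old = _DTYPE
    _DTYPE = np.dtype(dt)
    try:
        yield
    finally:
        _DTYPE = old

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "concat",
    "conv3d",
    "upsample2x",
    "avgpool2",
    "sigmoid",
    "softplus",
    "leaky_relu",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff --------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        if not (self.requires_grad or self._backward is not None):
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, float(exponent))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def item(self):
        return float(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _track(a: Tensor) -> bool:
    return a.requires_grad or a._backward is not None


def _make(data, parents, backward):
    if any(_track(p) for p in parents):
        return Tensor(data, parents=[p for p in parents if _track(p)], backward=backward)
    return Tensor(data)


# -- arithmetic ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if _track(a):
            a._accumulate(_unbroadcast(g, a.data.shape))
        if _track(b):
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if _track(a):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if _track(b):
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def backward(g):
        if _track(a):
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if _track(b):
            b._accumulate(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a: Tensor, exponent: float) -> Tensor:
    out_data = a.data ** exponent

    def backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(out_data, (a,), backward)


def texp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def tlog(a: Tensor) -> Tensor:
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


# -- pointwise nonlinearities -------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), overflow-safe."""
    x = a.data
    out_data = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        a._accumulate(g * s)

    return _make(out_data, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.1) -> Tensor:
    out_data = np.where(a.data >= 0, a.data, slope * a.data)

    def backward(g):
        a._accumulate(g * np.where(a.data >= 0, 1.0, slope))

    return _make(out_data, (a,), backward)


# -- reductions / shape -------------------------------------------------

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)

    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _track(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


# -- 3D convolution ------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """3D cross-correlation of (N, Cin, D, H, W) with (Cout, Cin, k, k, k)."""
    xd, wd, bd = x.data, w.data, b.data
    n, cin, d, h, wdim = xd.shape
    cout, cin_w, k = wd.shape[0], wd.shape[1], wd.shape[2]
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs weight {cin_w}")
    s, p = int(stride), int(padding)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]
    do, ho, wo = win.shape[2:5]
    nloc = do * ho * wo
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, nloc, cin * k * k * k)
    wmat = wd.reshape(cout, -1)
    out_mat = cols @ wmat.T + bd
    out_data = out_mat.transpose(0, 2, 1).reshape(n, cout, do, ho, wo)

    def backward(g):
        gres = np.ascontiguousarray(g.reshape(n, cout, nloc))
        if _track(w):
            gw = (gres @ cols).sum(axis=0)  # batched dgemm, (Cout, Cin*k^3)
            w._accumulate(gw.reshape(wd.shape))
        if _track(b):
            b._accumulate(gres.sum(axis=(0, 2)))
        if _track(x):
            colg = gres.transpose(0, 2, 1) @ wmat
            colg = colg.reshape(n, do, ho, wo, cin, k, k, k)
            colg = colg.transpose(0, 4, 5, 6, 7, 1, 2, 3)
            gxp = np.zeros_like(xp)
            for a in range(k):
                for bb in range(k):
                    for c in range(k):
                        gxp[:, :, a:a + s * do:s, bb:bb + s * ho:s, c:c + s * wo:s] += \
                            colg[:, :, a, bb, c]
            x._accumulate(gxp[:, :, p:p + d, p:p + h, p:p + wdim])

    return _make(out_data, (x, w, b), backward)


# -- resampling ----------------------------------------------------------

def _up2_last(x: np.ndarray) -> np.ndarray:
    # 1D factor-2 linear upsampling, align_corners=False, edge-clamped
    xl = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    xr = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * xl
    out[..., 1::2] = 0.75 * x + 0.25 * xr
    return out


def _up2_last_adjoint(g: np.ndarray) -> np.ndarray:
    ge, go = g[..., 0::2], g[..., 1::2]
    gx = 0.75 * ge + 0.75 * go
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return gx


def upsample2x(x: Tensor) -> Tensor:
    """Trilinear factor-2 upsampling of the spatial axes of (N, C, D, H, W)."""
    data = x.data
    for axis in (2, 3, 4):
        data = np.moveaxis(_up2_last(np.moveaxis(data, axis, -1)), -1, axis)

    def backward(g):
        for axis in (4, 3, 2):
            g = np.moveaxis(_up2_last_adjoint(np.moveaxis(g, axis, -1)), -1, axis)
        x._accumulate(g)

    return _make(data, (x,), backward)


def avgpool2(x: Tensor) -> Tensor:
    """2x2x2 mean-pool with stride 2 (spatial dims must be even)."""
    n, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {(d, h, w)}")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out_data = r.mean(axis=(3, 5, 7))

    def backward(g):
        gx = np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4) / 8.0
        x._accumulate(gx)

    return _make(out_data, (x,), backward)
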