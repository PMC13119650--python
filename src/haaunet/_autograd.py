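"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the segmentation network needs:
broadcast arithmetic, matmul, stride-1 "same" convolution (im2col),
2x2 max-pooling, stride-1 sliding max (grayscale morphology), bilinear
2x upsampling, sigmoid/ReLU/log-softmax, dropout, reductions and
concatenation.  Tensors are NHWC.  Gradients are accumulated by a
topological backward sweep over the recorded tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "slide_max",
           "slide_min", "standardize", "upsample_bilinear_2x", "dropout",
           "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._children: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, children, backward) -> "Tensor":
        out = Tensor(data)
        if any(c.requires_grad for c in children):
            out.requires_grad = True
            out._children = children
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            dtype = self.data.dtype if np.issubdtype(self.data.dtype,
                                                     np.floating) else np.float64
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for c in t._children:
                visit(c)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic ops ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        return Tensor._make(out_data, (self, other), back)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def back(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), back)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), back)

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def log(self):
        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def back(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), back)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                gg = np.expand_dims(gg, axes)
            self._accum(np.broadcast_to(gg, self.data.shape).copy()
                        if gg.shape != self.data.shape else gg)

        return Tensor._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=-1, keepdims=False):
        idx = self.data.argmax(axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def back(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            grad = np.zeros_like(self.data, dtype=np.float64)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        return Tensor._make(out_data, (self,), back)

    def reshape(self, *shape):
        old = self.data.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), back)

    def log_softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        s = self.data - m
        lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
        out_data = s - lse
        soft = np.exp(out_data)

        def back(g):
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), back)


# -- structured ops --------------------------------------------------------

def concat(tensors, axis=-1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(out_data, tuple(tensors), back)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation. x:(N,H,W,Ci) w:(kh,kw,Ci,Co)."""
    kh, kw, ci, co = w.shape
    ph, pw = kh // 2, kw // 2
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,Ci,kh,kw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * wd, kh * kw * ci)
    out = cols @ w.reshape(kh * kw * ci, co)
    return out.reshape(n, h, wd, co), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2D convolution (cross-correlation), NHWC."""
    kh, kw, ci, co = w.data.shape
    out_data, cols = _conv_same(x.data, w.data)
    if b is not None:
        out_data = out_data + b.data

    children = (x, w) if b is None else (x, w, b)

    def back(g):
        n, h, wd, _ = g.shape
        g2 = g.reshape(n * h * wd, co)
        if w.requires_grad:
            w._accum((cols.T @ g2).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            # full correlation with the spatially-flipped, channel-swapped kernel
            wf = w.data[::-1, ::-1].transpose(0, 1, 3, 2)
            dx, _ = _conv_same(g, wf)
            x._accum(dx)

    return Tensor._make(out_data, children, back)


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    r = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    rr = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = rr.argmax(axis=-1)
    out_data = np.take_along_axis(rr, idx[..., None], axis=-1)[..., 0]

    def back(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float64)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        x._accum(gr.reshape(n, h, w, c))

    return Tensor._make(out_data, (x,), back)


_FLAT_BASE_CACHE: dict = {}


def _flat_base(out_shape: tuple, pad_shape: tuple, axis: int):
    """Cached flat indices of out positions in the padded array (offset 0)."""
    key = (out_shape, pad_shape, axis)
    hit = _FLAT_BASE_CACHE.get(key)
    if hit is not None:
        return hit
    strides = np.empty(len(pad_shape), dtype=np.int64)
    strides[-1] = 1
    for i in range(len(pad_shape) - 2, -1, -1):
        strides[i] = strides[i + 1] * pad_shape[i + 1]
    base = np.zeros(out_shape, dtype=np.int64)
    for i, (sz, st) in enumerate(zip(out_shape, strides)):
        shape = [1] * len(out_shape)
        shape[i] = sz
        base = base + np.arange(sz, dtype=np.int64).reshape(shape) * st
    _FLAT_BASE_CACHE[key] = (base, int(strides[axis]))
    return base, int(strides[axis])


def _slide_max_1d(x: Tensor, k: int, axis: int) -> Tensor:
    """Stride-1 width-k max filter along one axis, same padding.

    Forward runs through scipy's C max filter; the argmax needed for the
    gradient scatter is computed lazily in the backward closure.
    """
    from scipy.ndimage import maximum_filter1d

    p = k // 2
    out_data = maximum_filter1d(x.data, k, axis=axis, mode="constant",
                                cval=-np.inf)

    def back(g):
        if not x.requires_grad:
            return
        pads = [(0, 0)] * x.data.ndim
        pads[axis] = (p, p)
        xp = np.pad(x.data, pads, constant_values=-np.inf)
        win = sliding_window_view(xp, k, axis=axis)
        idx = win.argmax(axis=-1)
        base, stride = _flat_base(out_data.shape, xp.shape, axis)
        flat = base + idx * stride
        gpad = np.bincount(flat.ravel(), weights=np.ravel(g).astype(np.float64),
                           minlength=int(np.prod(xp.shape))).reshape(xp.shape)
        sl = [slice(None)] * x.data.ndim
        sl[axis] = slice(p, p + x.data.shape[axis])
        x._accum(gpad[tuple(sl)])

    return Tensor._make(out_data, (x,), back)


def standardize(x: Tensor, axes=(1, 2, 3), eps: float = 1e-6) -> Tensor:
    """Zero-mean unit-variance standardization over `axes` as one fused op."""
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    z = (x.data - mu) * inv

    def back(g):
        if not x.requires_grad:
            return
        gm = g.mean(axis=axes, keepdims=True)
        gz = (g * z).mean(axis=axes, keepdims=True)
        x._accum((g - gm - z * gz) * inv)

    return Tensor._make(z, (x,), back)


def slide_max(x: Tensor, k: int) -> Tensor:
    """Stride-1 k x k max filter with same padding (grayscale dilation).

    The flat square structuring element is separable: a row max filter
    followed by a column max filter.
    """
    return _slide_max_1d(_slide_max_1d(x, k, 1), k, 2)


def slide_min(x: Tensor, k: int) -> Tensor:
    """Stride-1 k x k min filter (grayscale erosion)."""
    return -slide_max(-x, k)


def _interp_matrix(h: int) -> np.ndarray:
    """Bilinear 2x upsampling as a (2h, h) interpolation matrix."""
    a = np.zeros((2 * h, h))
    for i in range(2 * h):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), h - 1)
        hi_c = min(max(lo + 1, 0), h - 1)
        a[i, lo_c] += 1.0 - t
        a[i, hi_c] += t
    return a


_INTERP_CACHE: dict = {}


def upsample_bilinear_2x(x: Tensor) -> Tensor:
    n, h, w, c = x.data.shape
    dt = x.data.dtype
    ah = _INTERP_CACHE.setdefault((h, dt.str),
                                  _interp_matrix(h).astype(dt))
    aw = (_INTERP_CACHE.setdefault((w, dt.str), _interp_matrix(w).astype(dt))
          if w != h else ah)
    # out[n,p,q,c] = sum_{h,w} AH[p,h] AW[q,w] x[n,h,w,c]
    t = np.tensordot(ah, x.data, axes=(1, 1))        # (2H, N, W, C)
    out_data = np.tensordot(aw, t, axes=(1, 2))      # (2W, 2H, N, C)
    out_data = out_data.transpose(2, 1, 0, 3)

    def back(g):
        if not x.requires_grad:
            return
        t2 = np.tensordot(ah.T, g, axes=(1, 1))      # (H, N, 2W, C)
        dx = np.tensordot(aw.T, t2, axes=(1, 2))     # (W, H, N, C)
        x._accum(dx.transpose(2, 1, 0, 3))

    return Tensor._make(out_data, (x,), back)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = ((rng.random(x.data.shape) >= p) / (1.0 - p)).astype(x.data.dtype)

    def back(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), back)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
                      ).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
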