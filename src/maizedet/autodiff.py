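"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, but tensor-valued and with
the structured operations a two-stage detector needs: strided 2-D
convolution, bilinear gathering (the primitive behind deformable sampling
and RoI-Align), nearest upsampling, 2x2 max subsampling, and the detection
losses.  Everything is float64; gradients accumulate into ``Tensor.grad``
after :meth:`Tensor.backward`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "conv2d",
    "bilinear_gather",
    "upsample2x_nearest",
    "max_subsample2x",
    "gather_rows",
    "softmax_cross_entropy",
    "bce_with_logits",
    "smooth_l1",
    "concat",
]


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- plumbing ----------------------------------------------------------

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

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -out.grad * self.data / other.data ** 2, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bw():
            self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = bw if out.requires_grad else None
        return out

    # -- nonlinearities ----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))

        def bw():
            self._accum(out.grad * mask)

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor(s, parents=(self,))

        def bw():
            self._accum(out.grad * s * (1.0 - s))

        out._backward = bw if out.requires_grad else None
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))

        def bw():
            self._accum(out.grad * e)

        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw():
            self._accum(out.grad / self.data)

        out._backward = bw if out.requires_grad else None
        return out

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw():
            self._accum(out.grad.reshape(self.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes)

        def bw():
            self._accum(out.grad.transpose(inv))

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = bw if out.requires_grad else None
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# structured operations
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation of NCHW input with FCkk weights (zero padding)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    F, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels, weights expect {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]  # N,C,Ho,Wo,kh,kw
    y = np.einsum("nchwij,fcij->nfhw", win, w.data, optimize=True)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    if b is not None:
        bt = parents[2]
        y = y + bt.data.reshape(1, F, 1, 1)
    out = Tensor(y, parents=parents)

    def bw():
        g = out.grad  # N,F,Ho,Wo
        if w.requires_grad:
            w._accum(np.einsum("nchwij,nfhw->fcij", win, g, optimize=True))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            gwin = np.einsum("fcij,nfhw->nchwij", w.data, g, optimize=True)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride] += gwin[..., i, j]
            if pad:
                gxp = gxp[:, :, pad:-pad or None, pad:-pad or None]
            x._accum(gxp)

    out._backward = bw if out.requires_grad else None
    return out


def bilinear_gather(x: Tensor, ys, xs) -> Tensor:
    """Sample ``x`` (N,C,H,W) at continuous locations with the tent kernel.

    ``ys``/``xs`` have shape (N, M); out-of-grid locations contribute zero
    (zero padding).  Returns (N, C, M).  Gradients flow to ``x`` and, when
    the coordinates are themselves tensors, to ``ys`` and ``xs`` — this is
    what lets deformable-convolution offsets learn by backpropagation.
    """
    x = as_tensor(x)
    yt = ys if isinstance(ys, Tensor) else None
    xt = xs if isinstance(xs, Tensor) else None
    ya = yt.data if yt is not None else np.asarray(ys, dtype=np.float64)
    xa = xt.data if xt is not None else np.asarray(xs, dtype=np.float64)
    if not (np.isfinite(ya).all() and np.isfinite(xa).all()):
        raise ValueError("bilinear_gather: non-finite sampling location")
    N, C, H, W = x.shape
    M = ya.shape[1]

    y0 = np.floor(ya).astype(np.int64)
    x0 = np.floor(xa).astype(np.int64)
    fy = ya - y0
    fx = xa - x0

    corners = []  # (valid mask, clipped yi, clipped xi, weight, dwdfy, dwdfx)
    for dy, wy, dwy in ((0, 1.0 - fy, -1.0), (1, fy, 1.0)):
        for dx, wx, dwx in ((0, 1.0 - fx, -1.0), (1, fx, 1.0)):
            yi, xi = y0 + dy, x0 + dx
            valid = (yi >= 0) & (yi < H) & (xi >= 0) & (xi < W)
            corners.append((valid, np.clip(yi, 0, H - 1), np.clip(xi, 0, W - 1),
                            wy * wx, dwy * wx, wy * dwx))

    nidx = np.arange(N)[:, None]
    vals = np.zeros((N, C, M))
    cached = []
    for valid, yi, xi, wgt, dwy, dwx in corners:
        v = x.data[nidx[:, None], np.arange(C)[None, :, None],
                   yi[:, None, :], xi[:, None, :]]  # N,C,M
        v = v * valid[:, None, :]
        cached.append(v)
        vals += v * wgt[:, None, :]
    out = Tensor(vals, parents=tuple(p for p in (x, yt, xt) if p is not None))

    def bw():
        g = out.grad  # N,C,M
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for valid, yi, xi, wgt, _, _ in corners:
                contrib = g * (wgt * valid)[:, None, :]
                np.add.at(gx, (nidx[:, None], np.arange(C)[None, :, None],
                               yi[:, None, :], xi[:, None, :]), contrib)
            x._accum(gx)
        if yt is not None and yt.requires_grad:
            gy = np.zeros_like(ya)
            for (_, _, _, _, dwy, _), v in zip(corners, cached):
                gy += (g * v).sum(axis=1) * dwy
            yt._accum(gy)
        if xt is not None and xt.requires_grad:
            gx_ = np.zeros_like(xa)
            for (_, _, _, _, _, dwx), v in zip(corners, cached):
                gx_ += (g * v).sum(axis=1) * dwx
            xt._accum(gx_)

    out._backward = bw if out.requires_grad else None
    return out


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Replicate every pixel of an NCHW tensor into a 2x2 block."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 parents=(x,))

    def bw():
        x._accum(out.grad.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bw if out.requires_grad else None
    return out


def max_subsample2x(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even or 1)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H == 1 and W == 1:  # nothing to pool; identity keeps pyramids buildable
        return x * 1.0
    if H % 2 or W % 2:
        raise ValueError(f"max_subsample2x needs even spatial dims, got {H}x{W}")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 parents=(x,))

    def bw():
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], out.grad[..., None], axis=-1)
        g = gflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(g.reshape(N, C, H, W))

    out._backward = bw if out.requires_grad else None
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows ``x[idx]`` with scatter-add backward."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(x.data[idx], parents=(x,))

    def bw():
        g = np.zeros_like(x.data)
        np.add.at(g, idx, out.grad)
        x._accum(g)

    out._backward = bw if out.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])

    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (R,K) logits against integer labels (R,)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    R = len(labels)
    nll = -np.log(np.maximum(p[np.arange(R), labels], 1e-300))
    out = Tensor(nll.mean(), parents=(logits,))

    def bw():
        g = p.copy()
        g[np.arange(R), labels] -= 1.0
        logits._accum(out.grad * g / R)

    out._backward = bw if out.requires_grad else None
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    logits = as_tensor(logits)
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), parents=(logits,))

    def bw():
        logits._accum(out.grad * (_sigmoid(z) - t) / z.size)

    out._backward = bw if out.requires_grad else None
    return out


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) regression loss."""
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=np.float64)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    out = Tensor(loss.mean(), parents=(pred,))

    def bw():
        g = np.where(ad < beta, d / beta, np.sign(d))
        pred._accum(out.grad * g / d.size)

    out._backward = bw if out.requires_grad else None
    return out
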