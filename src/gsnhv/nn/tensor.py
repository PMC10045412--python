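"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sized for the convolutional blocks in this
package: elementwise arithmetic, reductions, concatenation, nearest
upsampling, reflect padding, and the two convolution primitives (dense
and depthwise with channel multiplier).  Arrays are float32 by default;
float64 passes through untouched so gradients can be finite-difference
checked at high precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class _NoGrad:
    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph references eagerly
                node._backward = None
                node._parents = ()
                node.grad = None

    # -- elementwise ------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * e * np.power(a.data, e - 1.0))

        return Tensor._make(np.power(a.data, e), (a,), bw)

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bw)

    def clamp(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside (lo, hi)."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bw)

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bw(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[idx] = g
                a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- spatial ops (N, C, H, W) -----------------------------------------

    def upsample2(self):
        """Nearest-neighbour x2 upsampling on the last two axes."""
        a = self
        n, c, h, w = a.data.shape

        def bw(g):
            if a.requires_grad:
                a._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out = np.repeat(np.repeat(a.data, 2, axis=2), 2, axis=3)
        return Tensor._make(out, (a,), bw)

    def pad_reflect2d(self, pad: int):
        """Reflect-pad the last two axes by `pad` pixels."""
        a = self
        n, c, h, w = a.data.shape
        rows = np.pad(np.arange(h), pad, mode="reflect")
        cols = np.pad(np.arange(w), pad, mode="reflect")

        def bw(g):
            if not a.requires_grad:
                return
            tmp = np.zeros((n, c, h, w + 2 * pad), dtype=g.dtype)
            for r in range(h + 2 * pad):
                tmp[:, :, rows[r]] += g[:, :, r]
            dx = np.zeros((n, c, h, w), dtype=g.dtype)
            for q in range(w + 2 * pad):
                dx[:, :, :, cols[q]] += tmp[:, :, :, q]
            a._accumulate(dx)

        out = a.data[:, :, rows[:, None], cols[None, :]]
        return Tensor._make(out, (a,), bw)

    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """Dense 2-D cross-correlation; weight is (O, C, kh, kw), no bias."""
        a, w = self, weight
        o, cin, kh, kw = w.data.shape
        if kh == 1 and kw == 1 and padding == 0:
            return self._conv1x1(w, stride)
        xp = (np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
              if padding else a.data)
        n = xp.shape[0]
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
        # materialize im2col once; reused by both forward GEMM and dW
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * kh * kw)
        out = (col @ w.data.reshape(o, -1).T).reshape(n, ho, wo, o)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))

        def bw(g):
            gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
                n * ho * wo, o)
            if w.requires_grad:
                dw = (gflat.T @ col).reshape(o, cin, kh, kw)
                w._accumulate(dw.astype(w.data.dtype))
            if a.requires_grad:
                if stride == 1:
                    # dx = g (suitably padded) correlated with the
                    # spatially flipped, channel-transposed kernel
                    pg = kh - 1 - padding
                    gp = np.pad(g, ((0, 0), (0, 0), (pg, pg), (pg, pg)))
                    gw = np.lib.stride_tricks.sliding_window_view(
                        gp, (kh, kw), axis=(2, 3))
                    gcol = np.ascontiguousarray(
                        gw.transpose(0, 2, 3, 1, 4, 5)).reshape(
                        -1, o * kh * kw)
                    wflip = np.ascontiguousarray(
                        w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                    ).reshape(cin, -1)
                    dx = (gcol @ wflip.T).reshape(
                        a.data.shape[0], a.data.shape[2], a.data.shape[3],
                        cin).transpose(0, 3, 1, 2)
                    a._accumulate(np.ascontiguousarray(dx))
                else:
                    dcol = (gflat @ w.data.reshape(o, -1)).reshape(
                        n, ho, wo, cin, kh, kw)
                    dxp = np.zeros_like(xp)
                    for i in range(kh):
                        for j in range(kw):
                            dxp[:, :, i:i + stride * ho:stride,
                                j:j + stride * wo:stride] += \
                                dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    if padding:
                        dxp = dxp[:, :, padding:-padding, padding:-padding]
                    a._accumulate(dxp)

        return Tensor._make(out, (a, w), bw)

    def _conv1x1(self, w: "Tensor", stride: int = 1):
        """Pointwise convolution as a single GEMM over flattened pixels."""
        a = self
        o, cin = w.data.shape[:2]
        xs = a.data[:, :, ::stride, ::stride] if stride != 1 else a.data
        n, _, h, wd = xs.shape
        x2 = np.ascontiguousarray(xs).reshape(n, cin, h * wd)
        wmat = w.data.reshape(o, cin)
        out = np.matmul(wmat, x2).reshape(n, o, h, wd)

        def bw(g):
            g2 = g.reshape(n, o, h * wd)
            if w.requires_grad:
                dw = np.einsum("nop,ncp->oc", g2, x2, optimize=True)
                w._accumulate(dw.reshape(w.data.shape).astype(w.data.dtype))
            if a.requires_grad:
                dxs = np.matmul(wmat.T, g2).reshape(n, cin, h, wd)
                if stride == 1:
                    a._accumulate(dxs)
                else:
                    dx = np.zeros_like(a.data)
                    dx[:, :, ::stride, ::stride] = dxs
                    a._accumulate(dx)

        return Tensor._make(out, (a, w), bw)

    def depthwise_conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """Depthwise cross-correlation with channel multiplier.

        weight is (C, m, kh, kw); output has C*m channels, channel c*m+j
        being x[:, c] filtered by weight[c, j].
        """
        a, w = self, weight
        c, m, kh, kw = w.data.shape
        xp = (np.pad(a.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
              if padding else a.data)
        n = xp.shape[0]
        ho = (xp.shape[2] - kh) // stride + 1
        wo = (xp.shape[3] - kw) // stride + 1
        # shift-and-add over the kh*kw taps: each tap is one broadcasted
        # multiply on a contiguous slice (no im2col materialization)
        taps = [(i, j, xp[:, :, i:i + stride * ho:stride,
                          j:j + stride * wo:stride])
                for i in range(kh) for j in range(kw)]
        out = np.zeros((n, c, m, ho, wo), dtype=xp.dtype)
        for i, j, sl in taps:
            out += sl[:, :, None] * w.data[None, :, :, i, j, None, None]
        out = np.ascontiguousarray(out.reshape(n, c * m, ho, wo))

        def bw(g):
            gr = g.reshape(n, c, m, ho, wo)
            if w.requires_grad:
                dw = np.empty_like(w.data)
                for i, j, sl in taps:
                    dw[:, :, i, j] = np.einsum("nchw,ncmhw->cm", sl, gr,
                                               optimize=True)
                w._accumulate(dw)
            if a.requires_grad:
                dxp = np.zeros_like(xp)
                for i, j, _ in taps:
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += np.einsum(
                            "ncmhw,cm->nchw", gr, w.data[:, :, i, j],
                            optimize=True)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                a._accumulate(dxp)

        return Tensor._make(out, (a, w), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), bw)
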