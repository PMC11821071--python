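"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core behind the network layers: a tape-based ``Tensor``
wrapping an ``ndarray``, a handful of element-wise and reduction primitives,
and custom 1-D convolution / transpose-convolution / max-pool ops whose
forward and backward passes run as batched BLAS matmuls on shifted views
(no im2col buffer).  Graph construction is skipped entirely when no input
requires gradients, so inference costs the same as plain numpy.

Dtype policy: the engine preserves the floating dtype of its inputs
(float32 for training throughput, float64 for high-precision checks).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "astensor",
    "sigmoid",
    "leaky_relu",
    "conv1d",
    "conv_transpose1d",
    "maxpool1d",
    "dropout",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g, own: bool = False):
        """Add ``g`` to the stored gradient.

        ``own=True`` asserts that ``g`` is a freshly allocated array no other
        node references, allowing it to be adopted without a defensive copy.
        """
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g if own else g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # release the subgraph eagerly so activation buffers can be
                # recycled while the sweep is still running
                t._backward = None
                t._parents = ()
                t.grad = None

    def zero_grad(self):
        self.grad = None

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, astensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g)
            if b.requires_grad:
                b._accum(g)

        return Tensor._node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accum(-g, own=True)

        return Tensor._node(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, astensor(other)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * b.data, own=True)
            if b.requires_grad:
                b._accum(g * a.data, own=True)

        return Tensor._node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = astensor(other)
        return self * b ** -1.0

    def __rtruediv__(self, other):
        return astensor(other) * self ** -1.0

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self
        out = a.data ** p

        def bwd(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1), own=True)

        return Tensor._node(out, (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full, own=True)

        return Tensor._node(a.data[idx], (a,), bwd)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape

        def bwd(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._node(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def bwd(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._node(a.data.transpose(axes), (a,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape))

        return Tensor._node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        a = self
        if axis is None:
            out = a.data.max()
            idx = np.unravel_index(np.argmax(a.data), a.data.shape)

            def bwd(g):
                if a.requires_grad:
                    full = np.zeros_like(a.data)
                    full[idx] = g
                    a._accum(full, own=True)

            return Tensor._node(out, (a,), bwd)

        out = a.data.max(axis=axis, keepdims=keepdims)
        arg = np.argmax(a.data, axis=axis)

        def bwd(g):
            if a.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                full = np.zeros_like(a.data)
                np.put_along_axis(
                    full, np.expand_dims(arg, axis), np.broadcast_to(gg, np.expand_dims(arg, axis).shape), axis
                )
                a._accum(full, own=True)

        return Tensor._node(out, (a,), bwd)

    def min(self, axis=None, keepdims=False):
        return -((-self).max(axis=axis, keepdims=keepdims))

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * sign, own=True)

        return Tensor._node(np.abs(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)

        def bwd(g):
            if a.requires_grad:
                a._accum(g * 0.5 / np.maximum(out, np.finfo(out.dtype).tiny), own=True)

        return Tensor._node(out, (a,), bwd)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- nonlinearities --------------------------------------------------------

def sigmoid(x) -> Tensor:
    a = astensor(x)
    out = expit(a.data)

    def bwd(g):
        if a.requires_grad:
            gi = (1.0 - out) * out
            gi *= g
            a._accum(gi, own=True)

    return Tensor._node(out, (a,), bwd)


def leaky_relu(x, negative_slope: float = 0.3) -> Tensor:
    a = astensor(x)
    pos = a.data > 0
    slope = a.data.dtype.type(negative_slope)
    out = np.where(pos, a.data, a.data * slope)

    def bwd(g):
        if a.requires_grad:
            a._accum(np.where(pos, g, g * slope), own=True)

    return Tensor._node(out, (a,), bwd)


# -- structured ops --------------------------------------------------------
#
# Sequence tensors are channels-last: (batch B, time L, channels C).  The
# stride-1 'same' convolution is evaluated as K batched GEMMs on shifted
# views of the padded input — no im2col buffer is ever materialized, and
# each per-sample slice is contiguous so BLAS runs copy-free.


def conv1d(x, W, b=None) -> Tensor:
    """Stride-1 'same' cross-correlation.

    x: (B, L, Cin); W: (K, Cin, Cout) with K odd; b: (Cout,) or None.
    Returns (B, L, Cout): ``y[b,t,o] = b[o] + sum_{k,c} x[b,t+k-K//2,c] W[k,c,o]``.
    """
    a, w = astensor(x), astensor(W)
    bt = astensor(b) if b is not None else None
    K = w.data.shape[0]
    if K % 2 == 0:
        raise ValueError("kernel length must be odd for 'same' padding")
    p = K // 2
    B, L, Cin = a.data.shape
    d = a.data

    def _ranges(k):
        # output rows t for which the input row t + (k - p) exists
        s = k - p
        return max(0, -s), min(L, L - s), s

    # centre tap covers the full length; edge taps accumulate on sub-slices
    y = np.matmul(d, w.data[p])
    for k in range(K):
        if k == p:
            continue
        lo, hi, s = _ranges(k)
        if lo < hi:
            y[:, lo:hi] += np.matmul(d[:, lo + s : hi + s], w.data[k])
    if bt is not None:
        y += bt.data

    parents = (a, w) if bt is None else (a, w, bt)

    def bwd(g):
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 1)), own=True)
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(K):
                lo, hi, s = _ranges(k)
                # (B, Cin, l) @ (B, l, Cout) batched, then reduce over batch
                gw[k] = np.matmul(
                    d[:, lo + s : hi + s].transpose(0, 2, 1), g[:, lo:hi]
                ).sum(axis=0)
            w._accum(gw, own=True)
        if a.requires_grad:
            wT = w.data.transpose(0, 2, 1)  # (K, Cout, Cin)
            # correlation of the output gradient with the flipped kernel
            gx = np.matmul(g, wT[p])
            for k in range(K):
                if k == p:
                    continue
                s = k - p
                lo, hi = max(0, s), min(L, L + s)
                gx[:, lo:hi] += np.matmul(g[:, lo - s : hi - s], wT[k])
            a._accum(gx, own=True)

    return Tensor._node(y, parents, bwd)


def _zero_stuff(x: Tensor, stride: int, offset: int, length: int) -> Tensor:
    """Place x[:, t, :] at time position offset + stride*t of a zero sequence."""
    a = astensor(x)
    B, L, C = a.data.shape
    out = np.zeros((B, length, C), dtype=a.data.dtype)
    sl = slice(offset, offset + stride * (L - 1) + 1, stride)
    out[:, sl, :] = a.data

    def bwd(g):
        if a.requires_grad:
            a._accum(g[:, sl, :])

    return Tensor._node(out, (a,), bwd)


def _flip_k(w: Tensor) -> Tensor:
    a = astensor(w)

    def bwd(g):
        if a.requires_grad:
            a._accum(g[::-1])

    return Tensor._node(np.ascontiguousarray(a.data[::-1]), (a,), bwd)


def conv_transpose1d(x, W, b=None, stride: int = 2) -> Tensor:
    """Fractionally-strided ('transpose') convolution producing stride*L samples.

    x: (B, L, Cin); W: (K, Cin, Cout) with K odd; b: (Cout,) or None.
    The full transpose-convolution output ``y[b, stride*t + k, o] +=
    x[b, t, c] W[k, c, o]`` (length stride*(L-1)+K) is cropped symmetrically
    to exactly stride*L samples, surplus going to the right edge.

    Implemented as zero-stuffing followed by a stride-1 correlation with the
    time-flipped kernel, which is algebraically identical and BLAS-friendly.
    """
    a, w = astensor(x), astensor(W)
    B, L, Cin = a.data.shape
    K = w.data.shape[0]
    if w.data.shape[1] != Cin:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {w.data.shape[1]}")
    if K < stride:
        raise ValueError("kernel must be at least as long as the stride")
    if K % 2 == 0:
        raise ValueError("kernel length must be odd")
    # offset aligning the 'same' correlation with the symmetric crop at
    # c0 = (K - stride) // 2 of the full transpose-convolution output
    offset = K - 1 - K // 2 - (K - stride) // 2
    if not 0 <= offset <= stride - 1 or stride * (L - 1) + offset >= stride * L:
        raise ValueError(f"unsupported stride/kernel combination ({stride}, {K})")
    z = _zero_stuff(a, stride, offset, stride * L)
    return conv1d(z, _flip_k(w), b)


def maxpool1d(x, k: int = 2) -> Tensor:
    """Non-overlapping max pooling over the time axis: (B, L, C) -> (B, L//k, C)."""
    a = astensor(x)
    B, L, C = a.data.shape
    if L % k:
        raise ValueError(f"time length {L} not divisible by pool size {k}")
    if k == 2:
        # branch-free pair max; ties route the gradient to the earlier sample
        a0, a1 = a.data[:, 0::2, :], a.data[:, 1::2, :]
        mask = a0 >= a1
        out = np.where(mask, a0, a1)

        def bwd(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[:, 0::2, :] = np.where(mask, g, 0)
                full[:, 1::2, :] = np.where(mask, 0, g)
                a._accum(full, own=True)

        return Tensor._node(out, (a,), bwd)

    xr = a.data.reshape(B, L // k, k, C)
    arg = np.argmax(xr, axis=2)
    out = np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        if a.requires_grad:
            full = np.zeros_like(xr)
            np.put_along_axis(full, arg[:, :, None, :], g[:, :, None, :], axis=2)
            a._accum(full.reshape(B, L, C), own=True)

    return Tensor._node(out, (a,), bwd)


def dropout(x, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    a = astensor(x)
    if rate <= 0.0:
        return a
    keep = (rng.random(a.data.shape) >= rate).astype(a.data.dtype)
    return a * Tensor(keep / (1.0 - rate))
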