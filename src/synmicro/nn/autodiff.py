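"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
``Tensor.backward()`` runs the tape in reverse topological order. The op set
is exactly what the 3D U-Net / PatchGAN stack needs: broadcast arithmetic,
pointwise nonlinearities, reductions, 3D convolution (any stride, zero
padding), instance normalization, 3D pixel shuffle and channel concatenation.

Array layout for spatial ops is ``(N, C, D, H, W)``. Convolutions are
computed by im2col (``sliding_window_view`` + one matmul); their input
gradient is a col2im scatter-add, so strided convolutions and their exact
gradients come out of one code path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "sub", "mul", "mean", "abs_", "square", "tanh",
    "sigmoid", "leaky_relu", "conv3d", "instance_norm", "pixel_shuffle3d",
    "concat_channels", "no_grad",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    __radd__ = __add__
    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_grad(*tensors) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data, dtype=g.dtype if t.data.dtype.kind != "f" else t.data.dtype)
    t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.asarray(a.data.mean())

    def backward(g):
        _accumulate(a, np.full_like(a.data, g / a.data.size))

    return _make(out_data, (a,), backward)


def abs_(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.abs(a.data)

    def backward(g):
        _accumulate(a, g * np.sign(a.data))

    return _make(out_data, (a,), backward)


def square(a) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** 2

    def backward(g):
        _accumulate(a, g * 2.0 * a.data)

    return _make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def tanh(a) -> Tensor:
    a = _as_tensor(a)
    y = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - y * y))

    return _make(y, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * y * (1.0 - y))

    return _make(y, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    pos = a.data > 0
    y = np.where(pos, a.data, slope * a.data)

    def backward(g):
        _accumulate(a, g * np.where(pos, 1.0, slope))

    return _make(y, (a,), backward)


# ---------------------------------------------------------------------------
# 3D convolution (im2col)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: tuple[int, int, int], stride: int):
    """(N, C, D', H', W', kd, kh, kw) strided view of a padded input."""
    v = sliding_window_view(xp, k, axis=(2, 3, 4))
    return v[:, :, ::stride, ::stride, ::stride]


def conv3d(x, w, b=None, stride: int = 1, pad: int = 1) -> Tensor:
    """3D cross-correlation: x (N,Ci,D,H,W) * w (Co,Ci,kd,kh,kw) + b (Co,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    b = _as_tensor(b) if b is not None else None
    N, Ci, D, H, W = x.data.shape
    Co, Ci2, kd, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, weight {Ci2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, (kd, kh, kw), stride)  # (N,Ci,Do,Ho,Wo,kd,kh,kw)
    _, _, Do, Ho, Wo, _, _, _ = cols.shape
    cols_mat = cols.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N * Do * Ho * Wo, Ci * kd * kh * kw)
    w_mat = w.data.reshape(Co, Ci * kd * kh * kw)
    out = (cols_mat @ w_mat.T).reshape(N, Do, Ho, Wo, Co).transpose(0, 4, 1, 2, 3)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1, 1)
    out = np.ascontiguousarray(out)

    def backward(g):
        g_mat = g.transpose(0, 2, 3, 4, 1).reshape(N * Do * Ho * Wo, Co)
        if w.requires_grad or w._parents:
            gw = (g_mat.T @ cols_mat).reshape(w.data.shape)
            _accumulate(w, gw)
        if b is not None and (b.requires_grad or b._parents):
            _accumulate(b, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            dcols = (g_mat @ w_mat).reshape(N, Do, Ho, Wo, Ci, kd, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        dxp[:, :,
                            i:i + Do * stride:stride,
                            j:j + Ho * stride:stride,
                            l:l + Wo * stride:stride] += dcols[..., i, j, l].transpose(0, 4, 1, 2, 3)
            gx = dxp[:, :, pad:pad + D, pad:pad + H, pad:pad + W] if pad else dxp
            _accumulate(x, gx)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------------
# instance normalization
# ---------------------------------------------------------------------------

def instance_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Per-(sample, channel) normalization over spatial axes with affine params."""
    x, gain, bias = _as_tensor(x), _as_tensor(gain), _as_tensor(bias)
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gview = gain.data.reshape(1, -1, 1, 1, 1)
    bview = bias.data.reshape(1, -1, 1, 1, 1)
    out = gview * xhat + bview

    def backward(g):
        if gain.requires_grad or gain._parents:
            _accumulate(gain, (g * xhat).sum(axis=(0, 2, 3, 4)))
        if bias.requires_grad or bias._parents:
            _accumulate(bias, g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad or x._parents:
            gy = g * gview
            m = gy.mean(axis=axes, keepdims=True)
            mx = (gy * xhat).mean(axis=axes, keepdims=True)
            _accumulate(x, inv * (gy - m - xhat * mx))

    return _make(out, (x, gain, bias), backward)


# ---------------------------------------------------------------------------
# pixel shuffle / concat
# ---------------------------------------------------------------------------

def pixel_shuffle3d(x, s: int = 2) -> Tensor:
    """Rearrange channel blocks of size s^3 into spatial resolution.

    (N, C, D, H, W) -> (N, C // s^3, D*s, H*s, W*s); C must divide by s^3.
    """
    x = _as_tensor(x)
    N, C, D, H, W = x.data.shape
    if C % (s ** 3) != 0:
        raise ValueError(f"channels {C} not divisible by s^3 = {s ** 3}")
    Co = C // s ** 3
    v = x.data.reshape(N, Co, s, s, s, D, H, W)
    out = np.ascontiguousarray(
        v.transpose(0, 1, 5, 2, 6, 3, 7, 4).reshape(N, Co, D * s, H * s, W * s)
    )

    def backward(g):
        gv = g.reshape(N, Co, D, s, H, s, W, s).transpose(0, 1, 3, 5, 7, 2, 4, 6)
        _accumulate(x, gv.reshape(N, C, D, H, W))

    return _make(out, (x,), backward)


def concat_channels(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        _accumulate(a, g[:, :ca])
        _accumulate(b, g[:, ca:])

    return _make(out, (a, b), backward)


class no_grad:
    """Context manager disabling tape construction (evaluation mode).

    Implemented by detaching at entry points; provided for API clarity in the
    training loop, where discriminator targets must not backpropagate into
    the generator.
    """

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
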