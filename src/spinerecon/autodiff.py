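"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the reconstruction network: 2D/3D "same"
convolutions (3x3(x3), stride 1, implemented as im2col matrix products),
2x max pooling, nearest-neighbour upsampling, ReLU/sigmoid, channel
concatenation, differentiable bilinear feature gathering (the
back-projection primitive), view averaging and a numerically stable
binary cross-entropy on logits.

Tensors are float32.  A :class:`Tensor` records its parents and a
closure computing parent gradients; ``backward`` runs a topological
sweep.  There is no broadcasting cleverness — every op states its exact
shapes — which keeps the implementation small and auditable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "relu",
    "sigmoid",
    "concat",
    "conv2d",
    "conv3d",
    "maxpool2d",
    "maxpool3d",
    "upsample2d",
    "upsample3d",
    "bilinear_gather",
    "mean_stack",
    "masked_mean_stack",
    "bce_with_logits",
    "channel_proj",
    "reshape",
]

_F32 = np.float32


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=None):
        self.data = np.ascontiguousarray(data, dtype=_F32)
        self.grad = None
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        if requires_grad is None:
            requires_grad = bool(parents) or grad_fn is not None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=_F32)
        for node in reversed(topo):
            if node.grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.grad_fn(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(_F32, copy=True)
                else:
                    parent.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b), lambda g: (g, g))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    s32 = s.astype(_F32)
    return Tensor(s32, (x,), lambda g: (g * s32 * (1.0 - s32),))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  tuple(tensors), grad_fn)


def channel_proj(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1(x1) convolution: x (Cin, *spatial), w (Cout, Cin), b (Cout,)."""
    cin = x.data.shape[0]
    spatial = x.data.shape[1:]
    xf = x.data.reshape(cin, -1)
    out = (w.data @ xf + b.data[:, None]).reshape((w.data.shape[0],) + spatial)

    def grad_fn(g):
        gf = g.reshape(w.data.shape[0], -1)
        gw = gf @ xf.T
        gb = gf.sum(axis=1)
        gx = (w.data.T @ gf).reshape(x.data.shape)
        return gx, gw, gb

    return Tensor(out, (x, w, b), grad_fn)


def reshape(x: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(x.data.reshape(shape), (x,),
                  lambda g: (g.reshape(x.data.shape),))


# ---------------------------------------------------------------- conv 2d/3d


def _conv_nd(x: Tensor, w: Tensor, b: Tensor, ndim: int) -> Tensor:
    """3^ndim 'same' convolution as a sum of shifted channel GEMMs.

    Each kernel offset contributes ``w[:, :, *off] @ x_shifted`` — one
    (Cout, Cin) x (Cin, N) matrix product on a contiguous slice copy.
    This keeps peak memory at a few copies of the activation instead of
    an im2col matrix 27x larger.
    """
    cin = x.data.shape[0]
    spatial = x.data.shape[1:]
    cout = w.data.shape[0]
    n = int(np.prod(spatial))
    pad = ((0, 0),) + ((1, 1),) * ndim
    xp = np.pad(x.data, pad)
    offsets = list(np.ndindex(*(3,) * ndim))

    def window(arr, off):
        sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
        return np.ascontiguousarray(arr[sl]).reshape(arr.shape[0], n)

    wmats = [np.ascontiguousarray(w.data[(slice(None), slice(None)) + off])
             for off in offsets]
    out = np.zeros((cout, n), dtype=_F32)
    for off, wm in zip(offsets, wmats):
        out += wm @ window(xp, off)
    out += b.data[:, None]

    def grad_fn(g):
        gf = g.reshape(cout, n)
        gb = gf.sum(axis=1)
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for off, wm in zip(offsets, wmats):
            xs = window(xp, off)
            gw[(slice(None), slice(None)) + off] = gf @ xs.T
            sl = (slice(None),) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial))
            gxp[sl] += (wm.T @ gf).reshape((cin,) + spatial)
        inner = (slice(None),) + (slice(1, -1),) * ndim
        return np.ascontiguousarray(gxp[inner]), gw, gb

    return Tensor(out.reshape((cout,) + spatial), (x, w, b), grad_fn)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 same convolution; x (Cin,H,W), w (Cout,Cin,3,3), b (Cout,)."""
    return _conv_nd(x, w, b, 2)


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3x3 same convolution; x (Cin,D,H,W), w (Cout,Cin,3,3,3)."""
    return _conv_nd(x, w, b, 3)


# ------------------------------------------------------------- pool/upsample


def maxpool2d(x: Tensor) -> Tensor:
    c, h, w = x.data.shape
    xr = x.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
    flat = xr.reshape(c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = (gf.reshape(c, h // 2, w // 2, 2, 2)
              .transpose(0, 1, 3, 2, 4).reshape(c, h, w))
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def maxpool3d(x: Tensor) -> Tensor:
    c, d, h, w = x.data.shape
    xr = (x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
          .transpose(0, 1, 3, 5, 2, 4, 6))
    flat = xr.reshape(c, d // 2, h // 2, w // 2, 8)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def grad_fn(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = (gf.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
              .transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w))
        return (gx,)

    return Tensor(out, (x,), grad_fn)


def upsample2d(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def grad_fn(g):
        return (g.reshape(c, h, 2, w, 2).sum(axis=(2, 4)),)

    return Tensor(out, (x,), grad_fn)


def upsample3d(x: Tensor) -> Tensor:
    c, d, h, w = x.data.shape
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2), 2, axis=3)

    def grad_fn(g):
        return (g.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)),)

    return Tensor(out, (x,), grad_fn)


# ------------------------------------------------------- bilinear back-proj


def bilinear_gather(fmap: Tensor, uv: np.ndarray, valid: np.ndarray) -> Tensor:
    """Sample a feature map at continuous pixel positions.

    ``fmap`` has shape (C, H, W); ``uv`` is (N, 2) of continuous (u, v)
    pixel coordinates (u along width); ``valid`` is an (N,) boolean.
    Each sample is the bilinear interpolation of the four surrounding
    pixels; samples that are invalid or whose whole support lies outside
    the map are zero.  The sampling positions are fixed geometry — only
    the feature map carries gradient.
    """
    c, h, w = fmap.data.shape
    u = uv[:, 0].astype(np.float64)
    v = uv[:, 1].astype(np.float64)
    u0 = np.floor(u).astype(np.int64)
    v0 = np.floor(v).astype(np.int64)
    fu = (u - u0).astype(_F32)
    fv = (v - v0).astype(_F32)

    corners = []
    flat_t = np.ascontiguousarray(fmap.data.reshape(c, h * w).T)  # (HW, C)
    acc = np.zeros((uv.shape[0], c), dtype=_F32)
    for du, dv, wgt in (
        (0, 0, (1 - fu) * (1 - fv)),
        (1, 0, fu * (1 - fv)),
        (0, 1, (1 - fu) * fv),
        (1, 1, fu * fv),
    ):
        ui = u0 + du
        vi = v0 + dv
        ok = valid & (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
        wgt = np.where(ok, wgt, 0.0).astype(_F32)
        idx = np.where(ok, vi * w + ui, 0)
        acc += flat_t[idx] * wgt[:, None]
        corners.append((idx, wgt))

    def grad_fn(g):
        gt = np.ascontiguousarray(g.T)  # (N, C)
        idx_all = np.concatenate([idx for idx, _ in corners])
        val_all = np.concatenate([gt * wgt[:, None] for _, wgt in corners])
        gacc = np.zeros((h * w, c), dtype=_F32)
        np.add.at(gacc, idx_all, val_all)
        return (gacc.T.reshape(c, h, w),)

    return Tensor(acc.T, (fmap,), grad_fn)


def masked_mean_stack(tensors: list[Tensor], masks: list[np.ndarray]) -> Tensor:
    """Per-element mean over the tensors whose mask is set.

    ``masks`` are boolean arrays broadcastable to each tensor's shape;
    elements where no mask is set yield zero.  Gradients flow scaled by
    mask / count.
    """
    count = np.zeros(tensors[0].data.shape, dtype=np.float64)
    acc = np.zeros(tensors[0].data.shape, dtype=np.float64)
    ms = []
    for t, m in zip(tensors, masks):
        m = np.broadcast_to(np.asarray(m, bool), t.data.shape)
        ms.append(m)
        count += m
        acc += t.data * m
    denom = np.maximum(count, 1.0)
    out = (acc / denom).astype(_F32)

    def grad_fn(g):
        gd = (g / denom).astype(_F32)
        return tuple(gd * m for m in ms)

    return Tensor(out, tuple(tensors), grad_fn)


def mean_stack(tensors: list[Tensor]) -> Tensor:
    """Elementwise mean over same-shaped tensors.

    Accumulation is in float64 and rounded once to float32, so the
    result is independent of the order of the inputs.
    """
    n = len(tensors)
    acc = np.zeros(tensors[0].data.shape, dtype=np.float64)
    for t in tensors:
        acc += t.data
    out = (acc / n).astype(_F32)

    def grad_fn(g):
        gi = g / n
        return tuple(gi for _ in tensors)

    return Tensor(out, tuple(tensors), grad_fn)


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against target.

    ``pos_weight`` scales the positive-class term (weight
    ``1 + (pos_weight - 1) * t`` per element), the usual counterweight
    for sparse foregrounds such as occupancy grids.
    """
    z = logits.data.astype(np.float64)
    t = np.asarray(target, dtype=np.float64)
    w = 1.0 + (pos_weight - 1.0) * t
    loss = w * (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    n = z.size

    def grad_fn(g):
        s = 1.0 / (1.0 + np.exp(-z))
        return ((w * (s - t) * (g / n)).astype(_F32),)

    return Tensor(np.float32(loss.mean()), (logits,), grad_fn)
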