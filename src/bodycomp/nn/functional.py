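"""Differentiable primitives for 3D segmentation networks.

All feature maps are channel-first float32 arrays of shape ``(C, D, H, W)``
with D the axial (slice) axis.  Convolutions use "same" zero padding and
stride 1; downsampling happens exclusively through 2x2x2 max-pooling and
upsampling through separable factor-2 linear interpolation (trilinear).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, accumulate_grad, make_op

__all__ = [
    "conv3d",
    "relu",
    "instance_norm",
    "max_pool3d",
    "upsample3d",
    "upsample_linear_axis",
    "concat_channels",
    "add",
    "softmax_channels",
]


# ---------------------------------------------------------------------------
# convolution

def _im2col(xp: np.ndarray, k: int, out_shape) -> np.ndarray:
    """Column matrix (C*k^3, N) of all kxkxk patches of the padded input."""
    c = xp.shape[0]
    d, h, w = out_shape
    cols = np.empty((c, k, k, k, d, h, w), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[:, i, j, l] = xp[:, i:i + d, j:j + h, l:l + w]
    return cols.reshape(c * k ** 3, d * h * w)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3D convolution, stride 1, same padding.

    ``weight`` has shape ``(c_out, c_in, k, k, k)`` with k odd (1 or 3 in
    practice).  Implemented as im2col + BLAS matmul; the adjoint scatters
    the column gradient back with the transposed kernel layout.
    """
    cout, cin, k, _, _ = weight.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv3d: expected {cin} input channels, got {x.shape[0]}")
    pad = k // 2
    spatial = x.shape[1:]
    if pad:
        xp = np.pad(x.value, ((0, 0),) + ((pad, pad),) * 3)
    else:
        xp = x.value
    cols = _im2col(xp, k, spatial) if k > 1 else x.value.reshape(cin, -1)
    wmat = weight.value.reshape(cout, cin * k ** 3)
    y = wmat @ cols
    if bias is not None:
        y += bias.value[:, None]
    y = y.reshape((cout,) + spatial)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(grad: np.ndarray) -> None:
        gmat = grad.reshape(cout, -1)
        if weight.requires_grad:
            accumulate_grad(weight, (gmat @ cols.T).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            accumulate_grad(bias, gmat.sum(axis=1))
        if x.requires_grad:
            if k == 1:
                accumulate_grad(x, (wmat.T @ gmat).reshape(x.shape))
                return
            # dx = correlation of the gradient with the flipped kernels
            gp = np.pad(grad, ((0, 0),) + ((pad, pad),) * 3)
            gcols = _im2col(gp, k, spatial)
            wflip = weight.value[:, :, ::-1, ::-1, ::-1]
            wf = wflip.transpose(1, 0, 2, 3, 4).reshape(cin, cout * k ** 3)
            accumulate_grad(x, (wf @ gcols).reshape(x.shape))

    return make_op(y, parents, backward)


# ---------------------------------------------------------------------------
# pointwise

def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    y = np.where(mask, x.value, 0.0).astype(np.float32)

    def backward(grad):
        if x.requires_grad:
            accumulate_grad(x, grad * mask)

    return make_op(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(grad):
        if a.requires_grad:
            accumulate_grad(a, grad)
        if b.requires_grad:
            accumulate_grad(b, grad)

    return make_op(a.value + b.value, (a, b), backward)


# ---------------------------------------------------------------------------
# instance normalization

def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes with learned affine.

    Suited to batch size 1, where batch statistics are unavailable.
    """
    c = x.shape[0]
    xv = x.value.reshape(c, -1)
    mu = xv.mean(axis=1, keepdims=True)
    var = xv.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xv - mu) * inv
    y = (gamma.value[:, None] * xhat + beta.value[:, None]).reshape(x.shape)

    def backward(grad):
        g = grad.reshape(c, -1)
        if gamma.requires_grad:
            accumulate_grad(gamma, (g * xhat).sum(axis=1))
        if beta.requires_grad:
            accumulate_grad(beta, g.sum(axis=1))
        if x.requires_grad:
            dxhat = g * gamma.value[:, None]
            m1 = dxhat.mean(axis=1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
            dx = inv * (dxhat - m1 - xhat * m2)
            accumulate_grad(x, dx.reshape(x.shape).astype(np.float32))

    return make_op(y.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling

def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max-pooling; spatial dims must be even."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"max_pool3d requires even spatial dims, got {(d, h, w)}")
    xr = x.value.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        if x.requires_grad:
            dxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
            np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
            dxr = dxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            dxr = dxr.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
            accumulate_grad(x, dxr)

    return make_op(y, (x,), backward)


# ---------------------------------------------------------------------------
# upsampling

def _upsample_axis_fwd(v: np.ndarray, axis: int) -> np.ndarray:
    """Factor-2 linear interpolation along one axis (half-pixel centers).

    out[2i]   = 0.75*v[i] + 0.25*v[i-1]   (edge clamped)
    out[2i+1] = 0.75*v[i] + 0.25*v[i+1]   (edge clamped)
    """
    v = np.moveaxis(v, axis, 0)
    prev = np.concatenate([v[:1], v[:-1]], axis=0)
    nxt = np.concatenate([v[1:], v[-1:]], axis=0)
    even = 0.75 * v + 0.25 * prev
    odd = 0.75 * v + 0.25 * nxt
    out = np.stack([even, odd], axis=1).reshape((2 * v.shape[0],) + v.shape[1:])
    return np.moveaxis(out, 0, axis).astype(np.float32)


def _upsample_axis_adj(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of `_upsample_axis_fwd` (transpose of the linear map)."""
    g = np.moveaxis(g, axis, 0)
    n2 = g.shape[0]
    ge = g[0:n2:2]
    go = g[1:n2:2]
    dv = 0.75 * (ge + go)
    # out[2(i+1)] pulls 0.25 from v[i]; out[2i-1] pulls 0.25 from v[i]
    dv[:-1] += 0.25 * ge[1:]
    dv[1:] += 0.25 * go[:-1]
    # clamped edges
    dv[0] += 0.25 * ge[0]
    dv[-1] += 0.25 * go[-1]
    return np.moveaxis(dv, 0, axis).astype(np.float32)


def upsample3d(x: Tensor) -> Tensor:
    """Trilinear factor-2 upsampling of all three spatial axes."""
    y = x.value
    for ax in (1, 2, 3):
        y = _upsample_axis_fwd(y, ax)

    def backward(grad):
        if x.requires_grad:
            g = grad
            for ax in (3, 2, 1):
                g = _upsample_axis_adj(g, ax)
            accumulate_grad(x, g)

    return make_op(y, (x,), backward)


def upsample_linear_axis(v: np.ndarray, axis: int, times: int = 1) -> np.ndarray:
    """Plain-array helper: repeated factor-2 linear upsampling along one axis."""
    for _ in range(times):
        v = _upsample_axis_fwd(v, axis)
    return v


# ---------------------------------------------------------------------------
# structural

def concat_channels(parts: list[Tensor]) -> Tensor:
    sizes = [p.shape[0] for p in parts]
    y = np.concatenate([p.value for p in parts], axis=0)

    def backward(grad):
        ofs = 0
        for p, s in zip(parts, sizes):
            if p.requires_grad:
                accumulate_grad(p, grad[ofs:ofs + s])
            ofs += s

    return make_op(y, tuple(parts), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis; per-voxel simplex output."""
    z = x.value - x.value.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)

    def backward(grad):
        if x.requires_grad:
            dot = (grad * p).sum(axis=0, keepdims=True)
            accumulate_grad(x, (p * (grad - dot)).astype(np.float32))

    return make_op(p.astype(np.float32), (x,), backward)
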