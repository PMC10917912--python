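"""Array-level neural-network operations with hand-written backward passes.

Convolution is evaluated by im2col + BLAS matmul; its gradient is the
matching col2im scatter.  Pooling, nearest-neighbour resizing and batch
normalisation follow the standard closed-form gradients.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import DTYPE, Tensor, is_grad_enabled


def _node(data, parents, backward) -> Tensor:
    if is_grad_enabled() and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), backward=backward)
    return Tensor(data)


def _pair(v) -> Tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, weight (out_c, in_c/groups, kh, kw)."""
    n, c, h, w = x.shape
    out_c, cg, kh, kw = weight.shape
    if c != cg * groups:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cg * groups}")
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (w + 2 * pw - kw) // sw + 1
    if oh <= 0 or ow <= 0:
        raise ValueError("conv2d: kernel larger than padded input")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    # (n, c, oh, ow, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    # (n, oh, ow, c, kh, kw) contiguous columns
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))

    og = out_c // groups
    outs = []
    wmat = weight.data.reshape(out_c, cg * kh * kw)
    for g in range(groups):
        colg = cols[:, :, :, g * cg:(g + 1) * cg].reshape(n * oh * ow, cg * kh * kw)
        outs.append(colg @ wmat[g * og:(g + 1) * og].T)
    y = outs[0] if groups == 1 else np.concatenate(outs, axis=1)
    y = y.reshape(n, oh, ow, out_c).transpose(0, 3, 1, 2)
    if bias is not None:
        y = y + bias.data.reshape(1, out_c, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gout):
        gy = gout.transpose(0, 2, 3, 1).reshape(n * oh * ow, out_c)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gout.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for g in range(groups):
                colg = cols[:, :, :, g * cg:(g + 1) * cg].reshape(n * oh * ow, cg * kh * kw)
                gw[g * og:(g + 1) * og] = (
                    gy[:, g * og:(g + 1) * og].T @ colg
                ).reshape(og, cg, kh, kw)
            weight._accumulate(gw)
        if x.requires_grad:
            gcols = np.empty_like(cols)
            for g in range(groups):
                gcolg = gy[:, g * og:(g + 1) * og] @ wmat[g * og:(g + 1) * og]
                gcols[:, :, :, g * cg:(g + 1) * cg] = gcolg.reshape(n, oh, ow, cg, kh, kw)
            # col2im: scatter window gradients back onto the padded input
            gxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
            gcols_t = gcols.transpose(0, 3, 1, 2, 4, 5)  # (n, c, oh, ow, kh, kw)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += gcols_t[:, :, :, :, i, j]
            gx = gxp[:, :, ph:ph + h, pw:pw + w] if (ph or pw) else gxp
            x._accumulate(gx)

    return _node(y, parents, backward)


# ---------------------------------------------------------------------------
# pooling and resizing
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int, stride: Optional[int] = None, padding: int = 0) -> Tensor:
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    n, c, h, w = x.shape
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (w + 2 * pw - kw) // sw + 1
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf)
        if (ph or pw)
        else x.data
    )
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::sh, ::sw]
    flat = win.reshape(n, c, oh, ow, kh * kw)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(gout):
        if not x.requires_grad:
            return
        gxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
        ohg, owg = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        hi = ohg[None, None] * sh + arg // kw
        wi = owg[None, None] * sw + arg % kw
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci, hi, wi), gout)
        gx = gxp[:, :, ph:ph + h, pw:pw + w] if (ph or pw) else gxp
        x._accumulate(gx)

    return _node(y, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, output_size) -> Tensor:
    """Average pooling to an arbitrary target grid (PyTorch-style bins)."""
    oh, ow = _pair(output_size)
    n, c, h, w = x.shape
    if h % oh == 0 and w % ow == 0:
        fh, fw = h // oh, w // ow
        y = x.data.reshape(n, c, oh, fh, ow, fw).mean(axis=(3, 5))

        def backward(gout):
            if not x.requires_grad:
                return
            g = gout[:, :, :, None, :, None] / (fh * fw)
            x._accumulate(np.broadcast_to(g, (n, c, oh, fh, ow, fw)).reshape(n, c, h, w).copy())

        return _node(y, (x,), backward)

    hs = [(i * h // oh, -(-(i + 1) * h // oh)) for i in range(oh)]
    ws = [(j * w // ow, -(-(j + 1) * w // ow)) for j in range(ow)]
    y = np.empty((n, c, oh, ow), dtype=DTYPE)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            y[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(gout):
        if not x.requires_grad:
            return
        gx = np.zeros((n, c, h, w), dtype=DTYPE)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                area = (h1 - h0) * (w1 - w0)
                gx[:, :, h0:h1, w0:w1] += gout[:, :, i:i + 1, j:j + 1] / area
        x._accumulate(gx)

    return _node(y, (x,), backward)


def global_avg_pool2d(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool2d(x: Tensor) -> Tensor:
    return x.max(axis=(2, 3), keepdims=True)


def upsample_nearest(x: Tensor, output_size) -> Tensor:
    oh, ow = _pair(output_size)
    n, c, h, w = x.shape
    rows = (np.arange(oh) * h) // oh
    cols = (np.arange(ow) * w) // ow
    y = x.data[:, :, rows][:, :, :, cols]

    def backward(gout):
        if not x.requires_grad:
            return
        gx = np.zeros((n, c, h, w), dtype=DTYPE)
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        ri = rows[None, None, :, None]
        cj = cols[None, None, None, :]
        np.add.at(gx, (ni, ci, ri, cj), gout)
        x._accumulate(gx)

    return _node(y, (x,), backward)


# ---------------------------------------------------------------------------
# normalisation and losses
# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    n, c, h, w = x.shape
    cnt = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        unbiased = var * cnt / max(cnt - 1, 1)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(gout):
        if gamma.requires_grad:
            gamma._accumulate((gout * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gout.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxhat = gout * gamma.data[None, :, None, None]
        if training:
            s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (gxhat - s1 / cnt - xhat * s2 / cnt) / std[None, :, None, None]
        else:
            gx = gxhat / std[None, :, None, None]
        x._accumulate(gx)

    return _node(y, (x, gamma, beta), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    p = np.exp(out)

    def backward(gout):
        if x.requires_grad:
            x._accumulate(gout - p * gout.sum(axis=axis, keepdims=True))

    return _node(out, (x,), backward)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under softmax logits."""
    targets = np.asarray(targets, dtype=np.int64)
    n, k = logits.shape
    ls = log_softmax(logits, axis=1)
    picked = ls[np.arange(n), targets]
    return -picked.mean()
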