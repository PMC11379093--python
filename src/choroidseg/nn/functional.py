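"""Differentiable array operations: 2-D convolution, bilinear resizing,
pooling and the segmentation loss.

Convolution is evaluated as a sum over kernel taps, each tap a batched
``einsum`` over a strided view of the padded input; the same loop yields the
exact adjoint for the backward pass.  Grouped and depthwise convolutions fall
out of the grouped view for free.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "bilinear_resize", "global_avg_pool", "cross_entropy"]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v), int(v))


def conv2d(x, w, bias=None, stride=1, padding=0, groups: int = 1) -> Tensor:
    """Cross-correlation of ``x`` [N,C,H,W] with ``w`` [C_out, C_in/groups, kh, kw]."""
    xt, wt = Tensor._coerce(x), Tensor._coerce(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    N, C, H, W = xt.shape
    Cout, Cg, kh, kw = wt.shape
    if C != Cg * groups:
        raise ValueError(
            f"conv2d: input has {C} channels but kernel expects {Cg * groups} "
            f"(groups={groups})"
        )
    if Cout % groups:
        raise ValueError("conv2d: output channels must be divisible by groups")
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("conv2d: kernel larger than padded input")

    xp = np.pad(xt.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    depthwise = groups == C and Cout == C  # one filter per channel
    dense = groups == 1
    wd = wt.data
    out = np.zeros((N, Cout, Ho, Wo))
    if not (depthwise or dense):
        xv = xp.reshape(N, groups, Cg, H + 2 * ph, W + 2 * pw)
        wv = wd.reshape(groups, Cout // groups, Cg, kh, kw)
    for u in range(kh):
        for v in range(kw):
            patch = xp[:, :, u : u + sh * Ho : sh, v : v + sw * Wo : sw]
            if depthwise:
                out += patch * wd[:, 0, u, v][None, :, None, None]
            elif dense:
                out += np.matmul(wd[:, :, u, v], patch.reshape(N, C, -1)).reshape(
                    N, Cout, Ho, Wo
                )
            else:
                pv = patch.reshape(N, groups, Cg, Ho, Wo)
                out += np.einsum(
                    "ngchw,goc->ngohw", pv, wv[:, :, :, u, v]
                ).reshape(N, Cout, Ho, Wo)

    def back(g):
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(wd)
        gm = g.reshape(N, Cout, -1) if dense else None
        for u in range(kh):
            for v in range(kw):
                patch = xp[:, :, u : u + sh * Ho : sh, v : v + sw * Wo : sw]
                dpatch = dxp[:, :, u : u + sh * Ho : sh, v : v + sw * Wo : sw]
                if depthwise:
                    dw[:, 0, u, v] += (patch * g).sum(axis=(0, 2, 3))
                    dpatch += g * wd[:, 0, u, v][None, :, None, None]
                elif dense:
                    pm = patch.reshape(N, C, -1)
                    dw[:, :, u, v] += np.matmul(
                        gm, pm.transpose(0, 2, 1)
                    ).sum(axis=0)
                    dpatch += np.matmul(wd[:, :, u, v].T, gm).reshape(
                        N, C, Ho, Wo
                    )
                else:
                    pv = patch.reshape(N, groups, Cg, Ho, Wo)
                    gv = g.reshape(N, groups, Cout // groups, Ho, Wo)
                    dw.reshape(groups, Cout // groups, Cg, kh, kw)[
                        :, :, :, u, v
                    ] += np.einsum("ngchw,ngohw->goc", pv, gv)
                    dpatch += np.einsum(
                        "ngohw,goc->ngchw", gv, wv[:, :, :, u, v]
                    ).reshape(N, C, Ho, Wo)
        dx = dxp[:, :, ph : ph + H, pw : pw + W]
        return dx, dw

    y = Tensor._make(out, (xt, wt), back)
    if bias is not None:
        bt = Tensor._coerce(bias)
        y = y + bt.reshape(1, Cout, 1, 1)
    return y


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D linear-interpolation matrix, half-pixel-centre
    (align_corners=False) convention with edge clamping."""
    i = np.arange(n_out)
    src = (i + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = src - i0
    m = np.zeros((n_out, n_in))
    np.add.at(m, (i, i0), 1.0 - t)
    np.add.at(m, (i, i1), t)
    return m


def bilinear_resize(x, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resampling of [N,C,H,W] to an exact output size."""
    xt = Tensor._coerce(x)
    N, C, H, W = xt.shape
    my = _interp_matrix(out_h, H)
    mx = _interp_matrix(out_w, W)
    out = np.einsum("oh,nchw->ncow", my, xt.data)
    out = np.einsum("pw,ncow->ncop", mx, out)

    def back(g):
        gy = np.einsum("pw,ncop->ncow", mx, g)
        return (np.einsum("oh,ncow->nchw", my, gy),)

    return Tensor._make(out, (xt,), back)


def global_avg_pool(x) -> Tensor:
    """Spatial mean: [N,C,H,W] -> [N,C]."""
    return Tensor._coerce(x).mean(axis=(2, 3))


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy of [N,K,H,W] logits against integer labels.

    For K=2 one-hot targets this equals binary cross-entropy on the softmax
    foreground probability.
    """
    target = np.asarray(target)
    k = logits.shape[1]
    onehot = np.eye(k)[target].transpose(0, 3, 1, 2)  # [N,K,H,W]
    ls = logits.log_softmax(axis=1)
    return -(ls * onehot).sum(axis=1).mean()


def binary_cross_entropy_logit(logit: Tensor, target: np.ndarray) -> Tensor:
    """Sigmoid BCE for a single foreground-logit channel [N,1,H,W]."""
    t = np.asarray(target, dtype=float)[:, None]
    p = logit.sigmoid()
    eps = 1e-12
    return -((p + eps).log() * t + (1.0 - p + eps).log() * (1.0 - t)).mean()
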