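"""Independent explicit-loop reference implementations.

These deliberately avoid the package's vectorised kernels: convolutions are
quadruple loops, attention is a per-query loop, interpolation is computed
pixel by pixel.  They define the expected values the fast paths are tested
against.
"""

import numpy as np


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v), int(v))


def conv2d_loop(x, w, b=None, stride=1, padding=0, groups=1):
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    n_, c_, h_, w_ = x.shape
    co, cg, kh, kw = w.shape
    ho = (h_ + 2 * ph - kh) // sh + 1
    wo = (w_ + 2 * pw - kw) // sw + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((n_, co, ho, wo))
    og = co // groups
    for n in range(n_):
        for o in range(co):
            g = o // og
            for i in range(ho):
                for j in range(wo):
                    s = 0.0
                    for c in range(cg):
                        for u in range(kh):
                            for v in range(kw):
                                s += w[o, c, u, v] * xp[
                                    n, g * cg + c, i * sh + u, j * sw + v
                                ]
                    out[n, o, i, j] = s + (b[o] if b is not None else 0.0)
    return out


def bilinear_loop(x, out_h, out_w):
    n_, c_, h_, w_ = x.shape
    out = np.zeros((n_, c_, out_h, out_w))
    for i in range(out_h):
        sy = min(max((i + 0.5) * h_ / out_h - 0.5, 0.0), h_ - 1.0)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, h_ - 1)
        ty = sy - y0
        for j in range(out_w):
            sx = min(max((j + 0.5) * w_ / out_w - 0.5, 0.0), w_ - 1.0)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, w_ - 1)
            tx = sx - x0
            out[:, :, i, j] = (
                (1 - ty) * (1 - tx) * x[:, :, y0, x0]
                + (1 - ty) * tx * x[:, :, y0, x1]
                + ty * (1 - tx) * x[:, :, y1, x0]
                + ty * tx * x[:, :, y1, x1]
            )
    return out


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def layernorm_loop(x, gamma, beta, eps=1e-5):
    out = np.empty_like(x)
    n_, c_, h_, w_ = x.shape
    for n in range(n_):
        for i in range(h_):
            for j in range(w_):
                col = x[n, :, i, j]
                m, v = col.mean(), col.var()
                out[n, :, i, j] = gamma * (col - m) / np.sqrt(v + eps) + beta
    return out


def batchnorm_eval_loop(x, gamma, beta, running_mean, running_var, eps=1e-5):
    rm = running_mean[None, :, None, None]
    rv = running_var[None, :, None, None]
    return gamma[None, :, None, None] * (x - rm) / np.sqrt(rv + eps) + beta[
        None, :, None, None
    ]


def acb_loop(x, weight, bias=None):
    """k×k + central-row 1×k + central-column k×1, branches summed."""
    k = weight.shape[2]
    c = k // 2
    out = conv2d_loop(x, weight, None, padding=(c, c))
    out += conv2d_loop(x, weight[:, :, c : c + 1, :], None, padding=(0, c))
    out += conv2d_loop(x, weight[:, :, :, c : c + 1], None, padding=(c, 0))
    if bias is not None:
        out += bias[None, :, None, None]
    return out


def _conv_of(mod, x):
    """Run a package Conv2d module's parameters through the loop oracle."""
    b = mod.bias.data if mod.bias is not None else None
    return conv2d_loop(x, mod.weight.data, b, mod.stride, mod.padding, mod.groups)


def psca_loop(x, psca):
    y1 = _conv_of(psca.point_path, x)
    y2 = _conv_of(psca.channel_path, x)
    y3 = _conv_of(
        psca.expand, _conv_of(psca.dw7_b, _conv_of(psca.reduce, _conv_of(psca.dw7_a, x)))
    )
    z = _conv_of(psca.fuse, np.concatenate([y1, y2, y3], axis=1))
    w = sigmoid(z)
    return x + w * x


def _acb_of(mod, x):
    b = mod.bias.data if mod.bias is not None else None
    return acb_loop(x, mod.weight.data, b)


def dfsm_loop(x, dfsm):
    n_, c_, h_, w_ = x.shape
    gap = x.mean(axis=(2, 3))  # [N,C]
    hidden = np.maximum(gap @ dfsm.fc1.weight.data + dfsm.fc1.bias.data, 0.0)
    a_c = sigmoid(hidden @ dfsm.fc2.weight.data + dfsm.fc2.bias.data)
    f_c = a_c[:, :, None, None] * x
    a_s = sigmoid(_acb_of(dfsm.spatial_acb_2, _acb_of(dfsm.spatial_acb_1, f_c)))
    f_s = a_s * f_c
    a_p = sigmoid(_conv_of(dfsm.point_conv, x))
    f_p = a_p * x
    return _conv_of(dfsm.out_conv, f_s + f_p)


def mhsa_loop(x, mhsa):
    """Exact attention (sr_ratio must be 1): per-query softmax loop."""
    assert mhsa.sr is None
    n_, c_, h_, w_ = x.shape
    heads = mhsa.heads
    d = c_ // heads
    t = x.reshape(n_, c_, h_ * w_).transpose(0, 2, 1)  # [N,T,C]
    q = t @ mhsa.q.weight.data + mhsa.q.bias.data
    k = t @ mhsa.k.weight.data + mhsa.k.bias.data
    v = t @ mhsa.v.weight.data + mhsa.v.bias.data
    tt = t.shape[1]
    out = np.zeros((n_, tt, c_))
    for n in range(n_):
        for hh in range(heads):
            sl = slice(hh * d, (hh + 1) * d)
            for i in range(tt):
                scores = np.array(
                    [q[n, i, sl] @ k[n, j, sl] / np.sqrt(d) for j in range(tt)]
                )
                e = np.exp(scores - scores.max())
                att = e / e.sum()
                out[n, i, sl] = sum(att[j] * v[n, j, sl] for j in range(tt))
    out = out @ mhsa.proj.weight.data + mhsa.proj.bias.data
    return out.transpose(0, 2, 1).reshape(n_, c_, h_, w_)


def patch_merge_eval_loop(x, pm):
    """Patch-merging oracle in inference mode (running-statistic BN)."""
    y = _conv_of(pm.dw, x)
    y = _conv_of(pm.pw, y)
    return batchnorm_eval_loop(
        y, pm.bn.gamma.data, pm.bn.beta.data,
        pm.bn._buffers["running_mean"], pm.bn._buffers["running_var"],
    )


def ffn_loop(x, ffn):
    from scipy.special import erf

    y = _conv_of(ffn.fc1, x)
    y = y * 0.5 * (1.0 + erf(y / np.sqrt(2.0)))
    return _conv_of(ffn.fc2, y)


def mixed_block_loop(x, block):
    y = x + mhsa_loop(
        layernorm_loop(x, block.norm1.gamma.data, block.norm1.beta.data),
        block.attn,
    )
    z = psca_loop(y, block.psca)
    return z + ffn_loop(
        layernorm_loop(z, block.norm2.gamma.data, block.norm2.beta.data),
        block.ffn,
    )


def dml_from_coarser_loop(x, dml, out_hw):
    return bilinear_loop(_conv_of(dml.proj, x), *out_hw)


def dml_from_finer_loop(x, dml):
    return _conv_of(dml.proj, _conv_of(dml.down, x))


def asff_loop(pyramid, asff):
    i = asff.i
    f = pyramid[i - 1]
    parts = []
    if asff.from_finer is not None:
        parts.append(dml_from_finer_loop(pyramid[i - 2], asff.from_finer) * f)
    parts.append(f + _acb_of(asff.enhance_acb, f))
    if asff.from_coarser is not None:
        parts.append(
            f * dml_from_coarser_loop(pyramid[i], asff.from_coarser,
                                      (f.shape[2], f.shape[3]))
        )
    return np.concatenate(parts, axis=1)


def decoder_loop(pyramid, dec, out_hw=None):
    h4, w4 = pyramid[0].shape[2], pyramid[0].shape[3]
    if out_hw is None:
        out_hw = (4 * h4, 4 * w4)
    feats = []
    for f, embed in zip(pyramid, dec.embeds):
        e = _conv_of(embed, f)
        if e.shape[2] != h4 or e.shape[3] != w4:
            e = bilinear_loop(e, h4, w4)
        feats.append(e)
    fused = _conv_of(dec.fuse, np.concatenate(feats, axis=1))
    logits = _conv_of(dec.classifier, fused)
    return bilinear_loop(logits, *out_hw)


def confusion_loop(pred, true, class_id):
    """Per-pixel loop tally of TP/FP/TN/FN."""
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p = pred[i, j] == class_id
            t = true[i, j] == class_id
            tp += p and t
            fp += p and not t
            tn += (not p) and (not t)
            fn += (not p) and t
    return tp, fp, tn, fn
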