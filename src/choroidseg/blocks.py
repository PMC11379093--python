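"""The three bespoke attention blocks of the architecture.

* :class:`ACB` — asymmetric convolution block: a k×k convolution whose
  central row and central column are re-applied as 1×k and k×1 branches.
  The asymmetric branches are *views* of the square kernel, so the block has
  exactly the parameter count of a plain k×k convolution; branch outputs are
  summed.
* :class:`PSCA` — parallel multiscale convolutional attention: point (1×1
  depthwise), channel (3×3 depthwise) and spatial (two 7×7 depthwise in
  series, bracketed by 1×1 channel reduce/expand at compression ratio ρ)
  paths, concatenated, fused by a 1×1 convolution, squashed by a sigmoid and
  applied as a multiplicative gate with a residual: out = x + σ(z) ⊙ x.
* :class:`DFSM` — dynamic feature selection: channel attention (global
  average pool → two-layer MLP → sigmoid), spatial attention (two large-kernel
  ACBs collapsing to a single-channel map), and point attention (1×1
  convolution), combined as out = Conv1×1(A_S ⊙ A_C ⊙ x + A_P ⊙ x).
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Conv2d, Linear, Module, Parameter, Tensor, concat, conv2d

__all__ = ["ACB", "PSCA", "DFSM", "acb_param_count"]


def _reduced(channels: int, ratio: int) -> int:
    """⌈C/ratio⌉, floored at one channel for narrow configurations."""
    return max(1, math.ceil(channels / ratio))


def acb_param_count(c_in: int, c_out: int, k: int) -> int:
    """Independent learnable scalars of an ACB: identical to a plain k×k
    convolution with bias, because the asymmetric branches share weights."""
    if k % 2 == 0:
        raise ValueError("ACB kernel size must be odd")
    return c_out * c_in * k * k + c_out


class ACB(Module):
    """Asymmetric convolution block (k×k + 1×k + k×1, shared weights, summed)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("ACB kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.k = k

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        if x.shape[1] != self.weight.shape[1]:
            raise ValueError(
                f"ACB expects {self.weight.shape[1]} channels, got {x.shape[1]}"
            )
        k, c = self.k, self.k // 2
        w = self.weight
        y = conv2d(x, w, padding=(c, c))
        y = y + conv2d(x, w[:, :, c : c + 1, :], padding=(0, c))
        y = y + conv2d(x, w[:, :, :, c : c + 1], padding=(c, 0))
        if self.bias is not None:
            y = y + self.bias.reshape(1, w.shape[0], 1, 1)
        return y


class PSCA(Module):
    """Parallel multiscale convolutional attention gate with residual."""

    def __init__(self, channels: int, ratio: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c, cr = channels, _reduced(channels, ratio)
        # all convolution paths are depthwise (groups == channels)
        self.point_path = Conv2d(c, c, 1, groups=c, rng=rng)
        self.channel_path = Conv2d(c, c, 3, padding=1, groups=c, rng=rng)
        self.dw7_a = Conv2d(c, c, 7, padding=3, groups=c, rng=rng)
        self.reduce = Conv2d(c, cr, 1, rng=rng)
        self.dw7_b = Conv2d(cr, cr, 7, padding=3, groups=cr, rng=rng)
        self.expand = Conv2d(cr, c, 1, rng=rng)
        self.fuse = Conv2d(3 * c, c, 1, rng=rng)
        self.channels = c

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"PSCA expects {self.channels} channels, got {x.shape[1]}"
            )
        y1 = self.point_path(x)
        y2 = self.channel_path(x)
        y3 = self.expand(self.dw7_b(self.reduce(self.dw7_a(x))))
        z = self.fuse(concat([y1, y2, y3], axis=1))
        w = z.sigmoid()
        return x + w * x


class DFSM(Module):
    """Dynamic feature selection: channel × spatial attention summed with
    point attention, projected to ``c_out``."""

    def __init__(self, channels: int, c_out: int, ratio: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c, cr = channels, _reduced(channels, ratio)
        self.fc1 = Linear(c, cr, rng=rng)
        self.fc2 = Linear(cr, c, rng=rng)
        self.spatial_acb_1 = ACB(c, cr, k=7, rng=rng)
        self.spatial_acb_2 = ACB(cr, 1, k=7, rng=rng)
        self.point_conv = Conv2d(c, c, 1, rng=rng)
        self.out_conv = Conv2d(c, c_out, 1, rng=rng)
        self.channels = c

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"DFSM expects {self.channels} channels, got {x.shape[1]}"
            )
        n, c = x.shape[0], x.shape[1]
        # channel attention: GAP -> MLP -> sigmoid, broadcast over space
        a_c = self.fc2(self.fc1(x.mean(axis=(2, 3))).relu()).sigmoid()
        f_c = a_c.reshape(n, c, 1, 1) * x
        # spatial attention: two large-kernel ACBs -> single-channel map
        a_s = self.spatial_acb_2(self.spatial_acb_1(f_c)).sigmoid()
        f_s = a_s * f_c
        # point attention on the raw input
        a_p = self.point_conv(x).sigmoid()
        f_p = a_p * x
        return self.out_conv(f_s + f_p)
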