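"""Local-enhanced hierarchical encoder.

Four stages, each a Patch Merging downsampler (3×3 depthwise stride-2
convolution + 1×1 channel projection + batch norm) followed by a stack of
mixed blocks.  A mixed block couples global and local modelling serially:

    y   = x + MHSA(LN(x))
    z   = PSCA(y)            # carries its own residual
    out = z + FFN(LN(z))

yielding a stride-4/8/16/32 pyramid with a doubling channel schedule.  The
stage-1 stem applies two stride-2 units to reach stride 4.  Self-attention
uses spatial-reduction ratios on keys/values (a strided convolution) so the
stride-4 stage is tractable on a CPU; ratio 1 recovers exact MHSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .blocks import PSCA
from .nn import (
    BatchNorm2d,
    Conv2d,
    LayerNorm2d,
    Linear,
    Module,
    Tensor,
)

__all__ = ["ModelConfig", "PatchMerging", "MHSA", "FFN", "MixedBlock", "Encoder"]


@dataclass
class ModelConfig:
    """Everything the architecture leaves configurable.

    The default is a desk-scale configuration sized for CPU training and
    testing; ``base()`` and ``paper_scale()`` provide progressively wider
    presets of the same four-stage, channel-doubling layout.
    """

    channels: tuple = (8, 16, 32, 64)
    depths: tuple = (1, 1, 1, 1)
    heads: tuple = (1, 2, 4, 8)
    sr_ratios: tuple = (8, 4, 2, 1)
    psca_ratio: int = 16
    dfsm_ratio: int = 16
    num_classes: int = 2
    decoder_dim: int = 32
    input_size: int = 256

    def __post_init__(self):
        for name in ("channels", "depths", "heads", "sr_ratios"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must list exactly four stages")
        for a, b in zip(self.channels, self.channels[1:]):
            if b != 2 * a:
                raise ValueError("channel schedule must double per stage")
        for c, h in zip(self.channels, self.heads):
            if c % h:
                raise ValueError("heads must divide the stage channel width")

    @classmethod
    def desk(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def base(cls) -> "ModelConfig":
        return cls(channels=(32, 64, 128, 256), depths=(1, 1, 2, 1),
                   decoder_dim=64, input_size=512)

    @classmethod
    def paper_scale(cls) -> "ModelConfig":
        return cls(channels=(64, 128, 256, 512), depths=(2, 2, 6, 2),
                   decoder_dim=256, input_size=512)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("channels", "depths", "heads", "sr_ratios"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class PatchMerging(Module):
    """Stride-2 downsampler: 3×3 depthwise conv, 1×1 projection, batch norm.

    Odd inputs are padded on the bottom/right before the strided convolution
    (pad-then-crop; never a silent resize)."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        self.dw = Conv2d(c_in, c_in, 3, stride=2, padding=1, groups=c_in, rng=rng)
        self.pw = Conv2d(c_in, c_out, 1, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.c_in = c_in

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        if x.shape[1] != self.c_in:
            raise ValueError(
                f"patch merging expects {self.c_in} channels, got {x.shape[1]}"
            )
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            pad_h, pad_w = h % 2, w % 2
            data = np.pad(x.data, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)),
                          mode="edge")
            x = Tensor(data)  # evaluation-path padding only
        return self.bn(self.pw(self.dw(x)))


class MHSA(Module):
    """Multi-head self-attention over flattened spatial tokens with optional
    spatial reduction of keys/values."""

    def __init__(self, channels: int, heads: int, sr_ratio: int = 1, rng=None):
        super().__init__()
        if channels % heads:
            raise ValueError("heads must divide channels")
        self.q = Linear(channels, channels, rng=rng)
        self.k = Linear(channels, channels, rng=rng)
        self.v = Linear(channels, channels, rng=rng)
        self.proj = Linear(channels, channels, rng=rng)
        self.sr = (
            Conv2d(channels, channels, sr_ratio, stride=sr_ratio, rng=rng)
            if sr_ratio > 1 else None
        )
        self.heads, self.channels, self.sr_ratio = heads, channels, sr_ratio

    def _tokens(self, x: Tensor):
        n, c, h, w = x.shape
        return x.reshape(n, c, h * w).transpose(0, 2, 1)  # [N, T, C]

    def forward(self, x, return_attention: bool = False):
        x = Tensor._coerce(x)
        n, c, h, w = x.shape
        nh, d = self.heads, c // self.heads
        q = self.q(self._tokens(x))
        src = self.sr(x) if self.sr is not None else x
        kv = self._tokens(src)
        k = self.k(kv)
        v = self.v(kv)
        tq, tk = q.shape[1], k.shape[1]
        q = q.reshape(n, tq, nh, d).transpose(0, 2, 1, 3)
        k = k.reshape(n, tk, nh, d).transpose(0, 2, 1, 3)
        v = v.reshape(n, tk, nh, d).transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(d))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(n, tq, c)
        out = self.proj(out).transpose(0, 2, 1).reshape(n, c, h, w)
        if return_attention:
            return out, att
        return out


class FFN(Module):
    """Position-wise feedforward: 1×1 conv C→eC, GELU, 1×1 conv eC→C."""

    def __init__(self, channels: int, expansion: int = 4, rng=None):
        super().__init__()
        self.fc1 = Conv2d(channels, expansion * channels, 1, rng=rng)
        self.fc2 = Conv2d(expansion * channels, channels, 1, rng=rng)

    def forward(self, x) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class MixedBlock(Module):
    """Serial MHSA → PSCA → FFN local-enhanced transformer block."""

    def __init__(self, channels: int, heads: int, sr_ratio: int,
                 psca_ratio: int = 16, rng=None):
        super().__init__()
        self.norm1 = LayerNorm2d(channels)
        self.attn = MHSA(channels, heads, sr_ratio, rng=rng)
        self.psca = PSCA(channels, psca_ratio, rng=rng)
        self.norm2 = LayerNorm2d(channels)
        self.ffn = FFN(channels, rng=rng)

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        x = x + self.attn(self.norm1(x))
        x = self.psca(x)
        return x + self.ffn(self.norm2(x))


class Encoder(Module):
    """Four-stage hierarchical encoder emitting [F1..F4] at strides 4/8/16/32."""

    def __init__(self, cfg: ModelConfig, in_channels: int = 1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = cfg.channels
        # stride-4 stem: two stride-2 patch-merging units
        self.stem_a = PatchMerging(in_channels, c[0], rng=rng)
        self.stem_b = PatchMerging(c[0], c[0], rng=rng)
        self.merges = [PatchMerging(c[i - 1], c[i], rng=rng) for i in (1, 2, 3)]
        self.stages = [
            [
                MixedBlock(c[i], cfg.heads[i], cfg.sr_ratios[i],
                           cfg.psca_ratio, rng=rng)
                for _ in range(cfg.depths[i])
            ]
            for i in range(4)
        ]
        self.cfg = cfg

    def _children(self):
        yield from super()._children()
        for i, stage in enumerate(self.stages):
            for j, blk in enumerate(stage):
                yield f"stages.{i}.{j}", blk

    def forward(self, x) -> list:
        x = Tensor._coerce(x)
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size must be a multiple of 32, got {h}x{w}"
            )
        x = self.stem_b(self.stem_a(x))
        pyramid = []
        for i in range(4):
            if i > 0:
                x = self.merges[i - 1](x)
            for blk in self.stages[i]:
                x = blk(x)
            pyramid.append(x)
        return pyramid
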