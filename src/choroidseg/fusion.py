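"""Adjacent multiscale feature fusion (ASFF).

Each pyramid level F_i is merged with dimension-matched neighbours:

    F_i^T      = F_i + ACB(F_i)                       (enhanced middle slot)
    from finer   = Conv1×1(DWConv3×3, stride 2)(F_{i-1})
    from coarser = UP×2(Conv1×1(F_{i+1}))
    out        = Concat(finer ⊙ F_i, F_i^T, F_i ⊙ coarser)

Boundary levels drop the missing neighbour term, so the fused map has 3·C_i
channels at interior levels and 2·C_i at the ends.  The multiplicative terms
gate against the *raw* current-level features.
"""

from __future__ import annotations

import numpy as np

from .blocks import ACB
from .nn import Conv2d, Module, Tensor, bilinear_resize, concat

__all__ = [
    "enhance",
    "dml_from_coarser",
    "dml_from_finer",
    "asff_forward",
    "DMLFromCoarser",
    "DMLFromFiner",
    "ASFF",
]


class DMLFromCoarser(Module):
    """Dimension-matching for the coarser neighbour: 1×1 conv halves the
    channels, then bilinear 2× upsampling (exact target size)."""

    def __init__(self, c_coarse: int, rng: np.random.Generator | None = None):
        super().__init__()
        if c_coarse % 2:
            raise ValueError("coarser level must have an even channel count")
        self.proj = Conv2d(c_coarse, c_coarse // 2, 1, rng=rng)

    def forward(self, x, out_hw=None) -> Tensor:
        x = Tensor._coerce(x)
        if out_hw is None:
            out_hw = (2 * x.shape[2], 2 * x.shape[3])
        return bilinear_resize(self.proj(x), *out_hw)


class DMLFromFiner(Module):
    """Dimension-matching for the finer neighbour: 3×3 stride-2 depthwise
    conv halves the resolution, then 1×1 conv doubles the channels."""

    def __init__(self, c_fine: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.down = Conv2d(c_fine, c_fine, 3, stride=2, padding=1,
                           groups=c_fine, rng=rng)
        self.proj = Conv2d(c_fine, 2 * c_fine, 1, rng=rng)

    def forward(self, x) -> Tensor:
        return self.proj(self.down(Tensor._coerce(x)))


class ASFF(Module):
    """Adjacent-level fusion for one pyramid stage ``i`` (1-based)."""

    def __init__(self, channels, i: int, rng: np.random.Generator | None = None):
        super().__init__()
        if not 1 <= i <= 4:
            raise ValueError("stage index must be in 1..4")
        self.i = i
        c = channels[i - 1]
        self.enhance_acb = ACB(c, c, 3, rng=rng)
        self.from_finer = DMLFromFiner(channels[i - 2], rng=rng) if i > 1 else None
        self.from_coarser = DMLFromCoarser(channels[i], rng=rng) if i < 4 else None
        self.out_channels = c * (1 + (i > 1) + (i < 4))

    def forward(self, pyramid) -> Tensor:
        i = self.i
        f = Tensor._coerce(pyramid[i - 1])
        parts = []
        if self.from_finer is not None:
            parts.append(self.from_finer(pyramid[i - 2]) * f)
        parts.append(f + self.enhance_acb(f))
        if self.from_coarser is not None:
            parts.append(f * self.from_coarser(pyramid[i], (f.shape[2], f.shape[3])))
        return concat(parts, axis=1)


# -- functional aliases matching the operation-level surface -----------------

def enhance(f, acb: ACB) -> Tensor:
    """Residual ACB enhancement of the current level: F + ACB(F)."""
    f = Tensor._coerce(f)
    return f + acb(f)


def dml_from_coarser(f_next, dml: DMLFromCoarser, out_hw=None) -> Tensor:
    return dml(f_next, out_hw)


def dml_from_finer(f_prev, dml: DMLFromFiner) -> Tensor:
    return dml(f_prev)


def _check_schedule(pyramid):
    for a, b in zip(pyramid, pyramid[1:]):
        if b.shape[1] != 2 * a.shape[1] or 2 * b.shape[2] != a.shape[2] \
                or 2 * b.shape[3] != a.shape[3]:
            raise ValueError(
                "pyramid violates the halve-resolution / double-channel schedule"
            )


def asff_forward(pyramid, i: int, asff: ASFF) -> Tensor:
    """Fuse stage ``i`` of a schedule-conforming pyramid."""
    if i != asff.i:
        raise ValueError("stage index does not match the fusion module")
    _check_schedule(pyramid)
    return asff(pyramid)
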