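"""All-MLP decode head.

Every pyramid level is mapped per-position to a shared embedding width,
bilinearly upsampled to the stride-4 grid, concatenated, fused and classified
by 1×1 (i.e. per-position linear) layers, then upsampled ×4 to the input
resolution.  Channel 0 is background, channel 1 the choroid; argmax ties
resolve to background.
"""

from __future__ import annotations

import numpy as np

from .encoder import ModelConfig
from .nn import Conv2d, Module, Tensor, bilinear_resize, concat

__all__ = ["AllMLPDecoder", "predict_mask"]


class AllMLPDecoder(Module):
    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        d = cfg.decoder_dim
        self.embeds = [Conv2d(c, d, 1, rng=rng) for c in cfg.channels]
        self.fuse = Conv2d(4 * d, d, 1, rng=rng)
        self.classifier = Conv2d(d, cfg.num_classes, 1, rng=rng)
        self.cfg = cfg

    def forward(self, pyramid, out_hw=None) -> Tensor:
        if len(pyramid) != 4:
            raise ValueError("decoder expects a four-level pyramid")
        for f, c in zip(pyramid, self.cfg.channels):
            if f.shape[1] != c:
                raise ValueError(
                    f"pyramid channels {[p.shape[1] for p in pyramid]} do not "
                    f"match the configured schedule {self.cfg.channels}"
                )
        h4, w4 = pyramid[0].shape[2], pyramid[0].shape[3]
        if out_hw is None:
            out_hw = (4 * h4, 4 * w4)
        feats = []
        for f, embed in zip(pyramid, self.embeds):
            e = embed(Tensor._coerce(f))
            if e.shape[2] != h4 or e.shape[3] != w4:
                e = bilinear_resize(e, h4, w4)
            feats.append(e)
        fused = self.fuse(concat(feats, axis=1))
        logits = self.classifier(fused)
        return bilinear_resize(logits, *out_hw)


def predict_mask(logits) -> np.ndarray:
    """Argmax over the two logit channels; ties go to background (0)."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    return (arr[:, 1] > arr[:, 0]).astype(np.uint8)
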