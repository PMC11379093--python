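import numpy as np
import pytest

from choroidseg import ModelConfig, SegDataset, SyntheticSpec, generate_bscan


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    """Narrow four-stage configuration for fast unit tests."""
    return ModelConfig(
        channels=(4, 8, 16, 32),
        depths=(1, 1, 1, 1),
        heads=(1, 2, 4, 8),
        sr_ratios=(2, 2, 1, 1),
        decoder_dim=8,
        input_size=64,
    )


def make_pyramid(rng, c1=4, hw=16, n=1):
    """Random schedule-conforming feature pyramid as numpy arrays."""
    return [
        rng.normal(size=(n, c1 * 2 ** i, hw // 2 ** i, hw // 2 ** i))
        for i in range(4)
    ]


@pytest.fixture
def probe_dataset():
    """Eight clean synthetic B-scans, train == val (overfit probe layout)."""
    spec = SyntheticSpec()
    pairs = [generate_bscan(spec, 100 + i) for i in range(8)]
    imgs = [p[0] for p in pairs]
    msks = [p[1] for p in pairs]
    return SegDataset(imgs + imgs, msks + msks,
                      splits=["train"] * 8 + ["val"] * 8)
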