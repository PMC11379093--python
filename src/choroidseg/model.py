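"""Network assembly and the fit/results front end.

:class:`ChoroidSegViT` wires the hierarchical encoder, per-stage adjacent
fusion + dynamic feature selection, and the all-MLP decode head into one
image → logits network.

:class:`ChoroidSegModel` is the modelling front end: construct it from a
dataset of B-scans and masks, call :meth:`fit`, and receive a
:class:`SegmentationResults` carrying the trained weights, the loss /
validation-metric history and a summary table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .blocks import DFSM
from .decoder import AllMLPDecoder, predict_mask
from .encoder import Encoder, ModelConfig
from .fusion import ASFF
from .metrics import SegReport, mean_metrics
from .nn import Module, Tensor, no_grad

__all__ = ["ChoroidSegViT", "ChoroidSegModel", "SegmentationResults"]


class ChoroidSegViT(Module):
    """Hybrid convolution/self-attention choroid segmentation network."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 in_channels: int = 1):
        super().__init__()
        cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, in_channels=in_channels, rng=rng)
        self.asff = [ASFF(cfg.channels, i, rng=rng) for i in (1, 2, 3, 4)]
        self.dfsm = [
            DFSM(self.asff[i].out_channels, cfg.channels[i], cfg.dfsm_ratio, rng=rng)
            for i in range(4)
        ]
        self.decoder = AllMLPDecoder(cfg, rng=rng)
        self.cfg = cfg

    def forward(self, x) -> Tensor:
        x = Tensor._coerce(x)
        pyramid = self.encoder(x)
        refined = [dfsm(asff(pyramid)) for asff, dfsm in zip(self.asff, self.dfsm)]
        return self.decoder(refined, out_hw=(x.shape[2], x.shape[3]))

    def predict(self, images) -> np.ndarray:
        """Binary masks [N,H,W] for [N,1,H,W] (or [N,H,W]) images in [0,1]."""
        arr = np.asarray(images, dtype=float)
        if arr.ndim == 3:
            arr = arr[:, None]
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                logits = self.forward(Tensor(arr))
        finally:
            self.train(was_training)
        return predict_mask(logits)

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})
        return self


@dataclass
class SegmentationResults:
    """Outcome of :meth:`ChoroidSegModel.fit`."""

    network: ChoroidSegViT
    history: list = field(default_factory=list)
    best_iteration: int = 0
    best_mdice: float = float("nan")
    val_report: SegReport | None = None
    seed: int = 0

    def predict(self, images) -> np.ndarray:
        return self.network.predict(images)

    def evaluate(self, images, masks) -> SegReport:
        preds = self.network.predict(images)
        return mean_metrics(list(preds), list(masks))

    def history_rows(self):
        return list(self.history)

    def save(self, path):
        self.network.save(path)

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.network.cfg
        print("Choroid segmentation fit", file=buf)
        print("=" * 48, file=buf)
        print(f"channels        : {cfg.channels}", file=buf)
        print(f"depths          : {cfg.depths}", file=buf)
        print(f"parameters      : {self.network.num_parameters()}", file=buf)
        print(f"seed            : {self.seed}", file=buf)
        print(f"best iteration  : {self.best_iteration}", file=buf)
        print(f"best val mDice  : {100.0 * self.best_mdice:.2f}", file=buf)
        if self.val_report is not None:
            s = self.val_report.scaled()
            print(
                f"final val       : mDice {s['mDice']:.2f}  "
                f"mIoU {s['mIoU']:.2f}  mAcc {s['mAcc']:.2f}",
                file=buf,
            )
        if self.history:
            last = self.history[-1]
            print(f"final loss      : {last['loss']:.4f}", file=buf)
        return buf.getvalue()


class ChoroidSegModel:
    """Statsmodels-style front end: data in the constructor, ``fit`` out.

    Parameters
    ----------
    dataset : pipeline.SegDataset
        Images, masks and split assignments.
    model_config, train_config : optional
        Architecture and optimisation settings; desk-scale defaults.
    """

    def __init__(self, dataset, model_config: ModelConfig | None = None,
                 train_config=None):
        from .pipeline import TrainConfig  # deferred; pipeline imports metrics

        self.dataset = dataset
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_directory(cls, data_dir, model_config=None, train_config=None):
        from .pipeline import load_dataset

        return cls(load_dataset(data_dir), model_config, train_config)

    def fit(self, seed: int | None = None) -> SegmentationResults:
        from .pipeline import train

        cfg = self.train_config
        if seed is not None:
            from dataclasses import replace

            cfg = replace(cfg, seed=seed)
        return train(self.model_config, cfg, self.dataset)
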