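"""Training, augmentation, evaluation and k-fold cross-validation.

Protocol: Adam at a constant learning rate of 5e-4, batch size 4, per-pixel
binary cross-entropy over the two-channel softmax, validation metrics every
``eval_interval`` iterations with the best-mDice weights retained.
Augmentation applies a horizontal flip, a small rotation and a contrast
rescale jointly to image and mask.  All randomness (weight init, shuffling,
augmentation draws) derives from a single seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .encoder import ModelConfig
from .metrics import SegReport, mean_metrics
from .model import ChoroidSegViT, SegmentationResults
from .nn import Adam, Tensor, cross_entropy, binary_cross_entropy_logit, no_grad

__all__ = [
    "TrainConfig",
    "SegDataset",
    "load_dataset",
    "augment",
    "train",
    "evaluate",
    "kfold_cv",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and augmentation settings (desk-scale defaults)."""

    lr: float = 5e-4
    batch: int = 4
    max_iters: int = 500
    eval_interval: int = 100
    seed: int = 0
    flip_p: float = 0.5
    max_rotation_deg: float = 10.0
    contrast_range: tuple = (0.8, 1.25)
    resize_to: int | None = 256
    loss: str = "softmax_ce"  # or "sigmoid_bce" on the foreground logit
    stop_at_fg_dice: float | None = None  # early stop once val foreground
    # dice reaches this level (best checkpoint is retained either way)

    def __post_init__(self):
        if self.lr <= 0 or self.batch < 1:
            raise ValueError("lr must be positive and batch >= 1")
        if self.eval_interval > self.max_iters:
            raise ValueError("eval_interval must not exceed max_iters")
        if self.loss not in ("softmax_ce", "sigmoid_bce"):
            raise ValueError("loss must be 'softmax_ce' or 'sigmoid_bce'")


@dataclass
class SegDataset:
    """Paired B-scans (float [H,W] in [0,1]) and binary masks with split and
    condition-tag bookkeeping."""

    images: list
    masks: list
    tags: list = field(default_factory=list)
    splits: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.images)
        if len(self.masks) != n:
            raise ValueError("images and masks must pair up")
        if not self.tags:
            self.tags = ["normal"] * n
        if not self.splits:
            self.splits = ["train"] * n

    def __len__(self):
        return len(self.images)

    def indices(self, split: str) -> list:
        return [i for i, s in enumerate(self.splits) if s == split]

    def subset(self, split: str) -> "SegDataset":
        idx = self.indices(split)
        return SegDataset(
            [self.images[i] for i in idx],
            [self.masks[i] for i in idx],
            [self.tags[i] for i in idx],
            [split] * len(idx),
        )


def load_dataset(data_dir) -> SegDataset:
    """Read a manifest-described directory of image/mask PNG pairs."""
    data_dir = Path(data_dir)
    images, masks, tags, splits = [], [], [], []
    with open(data_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(Image.open(data_dir / row["image"]), dtype=float) / 255.0
            mask = np.asarray(Image.open(data_dir / row["mask"]))
            masks.append((mask > 0).astype(np.uint8))
            images.append(img)
            tags.append(row["condition_tag"])
            splits.append(row["split"])
    return SegDataset(images, masks, tags, splits)


def _resize_pair(image, mask, size: int):
    if image.shape == (size, size):
        return image, mask
    img = _sk_resize(image, (size, size), order=1, preserve_range=True,
                     anti_aliasing=True)
    msk = _sk_resize(mask.astype(float), (size, size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return np.clip(img, 0.0, 1.0), (msk > 0.5).astype(np.uint8)


def augment(image, mask, rng: np.random.Generator,
            cfg: TrainConfig | None = None):
    """Jointly transform an image/mask pair: horizontal flip with probability
    ``flip_p``, rotation by a uniform angle within ±``max_rotation_deg``
    (bilinear for the image, nearest for the mask, out-of-frame filled with
    the darkest image intensity / label 0), and contrast rescaling about the
    image mean."""
    cfg = cfg or TrainConfig()
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)

    if rng.uniform() < cfg.flip_p:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    if angle != 0.0:
        background = float(image.min())
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=background)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)

    c = rng.uniform(*cfg.contrast_range)
    if c != 1.0:
        m = image.mean()
        image = np.clip(c * (image - m) + m, 0.0, 1.0)
    return image, mask.astype(np.uint8)


def _loss_fn(cfg: TrainConfig, logits: Tensor, targets: np.ndarray) -> Tensor:
    if cfg.loss == "sigmoid_bce":
        fg = logits[:, 1:2] - logits[:, 0:1]
        return binary_cross_entropy_logit(fg, targets)
    return cross_entropy(logits, targets)


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          dataset: SegDataset, log_path=None) -> SegmentationResults:
    """Fit the network on the dataset's train split, monitoring the val split.

    Returns a :class:`SegmentationResults` whose network carries the
    best-validation-mDice weights.
    """
    train_idx = dataset.indices("train")
    val_idx = dataset.indices("val")
    if not train_idx:
        raise ValueError("dataset has no train split")
    if not val_idx:
        raise ValueError("dataset has no val split")

    size = train_cfg.resize_to
    prep = [
        _resize_pair(dataset.images[i], dataset.masks[i], size)
        if size else (dataset.images[i], dataset.masks[i])
        for i in train_idx
    ]
    val_images = [
        (_resize_pair(dataset.images[i], dataset.masks[i], size)
         if size else (dataset.images[i], dataset.masks[i]))
        for i in val_idx
    ]

    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 17]))
    net = ChoroidSegViT(model_cfg, seed=train_cfg.seed)
    opt = Adam(net.parameters(), lr=train_cfg.lr)

    history, order, cursor = [], [], 0
    best = (-1.0, 0, None)  # (mdice, iteration, state)
    for it in range(1, train_cfg.max_iters + 1):
        batch_img, batch_msk = [], []
        for _ in range(train_cfg.batch):
            if cursor == 0:
                order = list(rng.permutation(len(prep)))
            img, msk = prep[order[cursor]]
            cursor = (cursor + 1) % len(prep)
            img, msk = augment(img, msk, rng, train_cfg)
            batch_img.append(img)
            batch_msk.append(msk)
        x = Tensor(np.stack(batch_img)[:, None])
        t = np.stack(batch_msk).astype(int)

        net.train()
        logits = net(x)
        loss = _loss_fn(train_cfg, logits, t)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}; aborting"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()

        row = {"iter": it, "loss": float(loss.data)}
        if it % train_cfg.eval_interval == 0 or it == train_cfg.max_iters:
            report = evaluate(net, [v[0] for v in val_images],
                              [v[1] for v in val_images])
            fg = report.per_class[1]["dice"]
            row.update(mDice=report.mDice, mIoU=report.mIoU,
                       mAcc=report.mAcc, fg_dice=fg)
            if report.mDice > best[0]:
                best = (report.mDice, it, net.state_dict())
            history.append(row)
            if (train_cfg.stop_at_fg_dice is not None
                    and fg >= train_cfg.stop_at_fg_dice):
                break
        else:
            history.append(row)

    if best[2] is not None:
        net.load_state_dict(best[2])
    net.eval()
    final = evaluate(net, [v[0] for v in val_images], [v[1] for v in val_images])

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["iter", "loss", "mDice", "mIoU", "mAcc", "fg_dice"]
            )
            writer.writeheader()
            writer.writerows(history)

    return SegmentationResults(
        network=net,
        history=history,
        best_iteration=best[1],
        best_mdice=best[0],
        val_report=final,
        seed=train_cfg.seed,
    )


def _pad_to_multiple(img: np.ndarray, multiple: int = 32):
    h, w = img.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    return img, (h, w)


def evaluate(network: ChoroidSegViT, images, masks) -> SegReport:
    """Deterministic inference-mode evaluation; inputs whose size is not a
    multiple of 32 are edge-padded and scored on the unpadded region."""
    images, masks = list(images), list(masks)
    if not images:
        raise ValueError("empty evaluation split")
    preds = []
    for img in images:
        padded, (h, w) = _pad_to_multiple(np.asarray(img, dtype=float))
        pred = network.predict(padded[None])[0, :h, :w]
        preds.append(pred)
    return mean_metrics(preds, masks)


def _stratified_folds(tags, k: int, rng: np.random.Generator):
    """Disjoint, exhaustive fold assignment, round-robin within each tag."""
    tags = np.asarray(tags)
    fold = np.empty(len(tags), dtype=int)
    cursor = 0  # continues across tags so fold sizes stay balanced
    for tag in np.unique(tags):
        idx = np.flatnonzero(tags == tag)
        idx = idx[rng.permutation(len(idx))]
        for i in idx:
            fold[i] = cursor % k
            cursor += 1
    return fold


def kfold_cv(dataset: SegDataset, k: int, model_cfg: ModelConfig,
             train_cfg: TrainConfig, seed: int | None = None) -> dict:
    """k-fold cross-validation with tag-stratified folds.

    Each fold trains on the other k−1 parts (holding ~10% of them out as the
    monitoring split) and is scored on the held-out part.  Returns per-fold
    reports plus mean/std of each metric across folds.
    """
    n = len(dataset)
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    seed = train_cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    fold_of = _stratified_folds(dataset.tags, k, rng)

    fold_reports = []
    for f in range(k):
        test_idx = [i for i in range(n) if fold_of[i] == f]
        rest = [i for i in range(n) if fold_of[i] != f]
        n_val = max(1, len(rest) // 10)
        val_set = set(rest[:n_val])
        ds = SegDataset(
            [dataset.images[i] for i in rest],
            [dataset.masks[i] for i in rest],
            [dataset.tags[i] for i in rest],
            ["val" if i in val_set else "train" for i in rest],
        )
        res = train(model_cfg, replace(train_cfg, seed=seed + f), ds)
        size = train_cfg.resize_to
        pairs = [
            _resize_pair(dataset.images[i], dataset.masks[i], size)
            if size else (dataset.images[i], dataset.masks[i])
            for i in test_idx
        ]
        report = evaluate(res.network, [p[0] for p in pairs],
                          [p[1] for p in pairs])
        fold_reports.append(report)

    summary = {}
    for key in ("mDice", "mIoU", "mAcc"):
        vals = [getattr(r, key) for r in fold_reports]
        summary[key] = {"mean": float(np.mean(vals)), "std": float(np.std(vals))}
    return {"folds": fold_reports, "summary": summary,
            "fold_assignment": fold_of.tolist()}
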