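"""Seeded generator of OCT-like layered B-scans with exact choroid masks.

A B-scan is rendered as a stack of horizontal bands separated by smooth
per-column boundary curves: dark vitreous, a retinal band, a thin bright RPE
line, a textured choroid band, and sclera below a low-contrast
choroid–scleral interface (CSI).  Each boundary is a mean depth plus a small
sum of random-phase harmonics.  The choroid band carries dark elliptical
vessel lumina and the whole image is degraded by multiplicative speckle.
The label mask marks exactly the choroid band (``rpe_bottom < y <= csi``)
and is computed from the noise-free curves, so no noise parameter can leak
into the labels.

The CSI contrast knob ``csi_contrast`` is the choroid-minus-sclera intensity
gap: at 0 the inferior boundary is invisible in the image (maximally fuzzy
CSI) while the mask is unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SyntheticSpec",
    "sample_boundaries",
    "generate_bscan",
    "generate_arrays",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry, intensity and noise parameters of the simulator (pixels and
    relative reflectance units)."""

    height: int = 256
    width: int = 256
    n_harmonics: int = 3
    boundary_amplitude: float | None = None  # default height/20
    vitreous_depth: float | None = None      # mean ILM depth; default height/4
    retina_thickness: float | None = None    # default height/8
    choroid_thickness: float | None = None   # default height/5
    rpe_thickness: float = 3.0
    vitreous_intensity: float = 0.08
    retina_intensity: float = 0.45
    rpe_intensity: float = 0.90
    choroid_intensity: float = 0.50
    csi_contrast: float = 0.20               # choroid minus sclera
    vessel_density: float = 0.15
    vessel_intensity: float = 0.15
    speckle_sigma: float = 0.08
    speckle_model: str = "gaussian"          # or "gamma"
    condition_tag: str = "normal"

    def __post_init__(self):
        h = self.height
        object.__setattr__(self, "boundary_amplitude",
                           h / 20 if self.boundary_amplitude is None
                           else float(self.boundary_amplitude))
        object.__setattr__(self, "vitreous_depth",
                           h / 4 if self.vitreous_depth is None
                           else float(self.vitreous_depth))
        object.__setattr__(self, "retina_thickness",
                           h / 8 if self.retina_thickness is None
                           else float(self.retina_thickness))
        object.__setattr__(self, "choroid_thickness",
                           h / 5 if self.choroid_thickness is None
                           else float(self.choroid_thickness))
        if min(self.retina_thickness, self.choroid_thickness,
               self.rpe_thickness) <= 0:
            raise ValueError("layer thicknesses must be positive")
        if not 0.0 <= self.csi_contrast <= 0.25:
            raise ValueError("csi_contrast must lie in [0, 0.25]")
        if not 0.0 <= self.vessel_density <= 1.0:
            raise ValueError("vessel_density must lie in [0, 1]")
        if self.speckle_model not in ("gaussian", "gamma"):
            raise ValueError("speckle_model must be 'gaussian' or 'gamma'")
        amp = self.boundary_amplitude
        # worst-case harmonic excursion is +-amp per curve; reject any
        # configuration that could let adjacent curves touch or leave the frame
        gap_top = self.retina_thickness + self.rpe_thickness
        if gap_top <= 2 * amp or self.choroid_thickness <= 2 * amp:
            raise ValueError(
                "boundary amplitude admits curve crossing for the configured "
                "layer thicknesses"
            )
        csi_mean = (self.vitreous_depth + gap_top + self.choroid_thickness)
        if self.vitreous_depth - amp < 1 or csi_mean + amp > h - 1:
            raise ValueError("boundary curves may leave the image frame")

    @property
    def sclera_intensity(self) -> float:
        return self.choroid_intensity - self.csi_contrast

    def lesioned(self) -> "SyntheticSpec":
        """Variant emulating pathology: thicker choroid, fuzzier CSI."""
        return replace(
            self,
            choroid_thickness=1.25 * self.choroid_thickness,
            csi_contrast=0.5 * self.csi_contrast,
            condition_tag="lesioned",
        )


def _curve(rng: np.random.Generator, mean: float, spec: SyntheticSpec) -> np.ndarray:
    x = np.arange(spec.width)
    y = np.full(spec.width, float(mean))
    per = spec.boundary_amplitude / spec.n_harmonics
    for k in range(1, spec.n_harmonics + 1):
        a = rng.uniform(0.0, per)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        y += a * np.sin(2.0 * np.pi * k * x / spec.width + phi)
    return y


def sample_boundaries(spec: SyntheticSpec, seed: int):
    """Per-column (ilm, rpe_bottom, csi) depth curves; strictly ordered."""
    rng = np.random.default_rng(seed)
    ilm = _curve(rng, spec.vitreous_depth, spec)
    rpe_bottom = _curve(
        rng, spec.vitreous_depth + spec.retina_thickness + spec.rpe_thickness, spec
    )
    csi = _curve(
        rng,
        spec.vitreous_depth + spec.retina_thickness + spec.rpe_thickness
        + spec.choroid_thickness,
        spec,
    )
    assert (ilm < rpe_bottom).all() and (rpe_bottom < csi).all()
    return ilm, rpe_bottom, csi


def _mask_from_curves(spec: SyntheticSpec, rpe_bottom, csi) -> np.ndarray:
    y = np.arange(spec.height)[:, None]
    return ((y > rpe_bottom[None, :]) & (y <= csi[None, :])).astype(np.uint8)


def generate_bscan(spec: SyntheticSpec, seed: int):
    """One (image, mask) pair: image float in [0,1] of shape [H,W], mask in
    {0,1}.  Fully determined by (spec, seed)."""
    ilm, rpe_bottom, csi = sample_boundaries(spec, seed)
    h, w = spec.height, spec.width
    y = np.arange(h)[:, None]
    rpe_top = rpe_bottom - spec.rpe_thickness

    img = np.full((h, w), spec.vitreous_intensity)
    img[(y > ilm[None, :]) & (y <= rpe_top[None, :])] = spec.retina_intensity
    img[(y > rpe_top[None, :]) & (y <= rpe_bottom[None, :])] = spec.rpe_intensity
    choroid = (y > rpe_bottom[None, :]) & (y <= csi[None, :])
    img[choroid] = spec.choroid_intensity
    img[y > csi[None, :]] = spec.sclera_intensity

    # vessel lumina: dark ellipses confined to the choroid band
    if spec.vessel_density > 0:
        vrng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        area = float(choroid.sum())
        mean_vessel_area = np.pi * 3.5 * 5.5  # mean ry * mean rx
        n_vessels = int(round(spec.vessel_density * area / mean_vessel_area))
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_vessels):
            cx = vrng.uniform(0, w)
            col = int(np.clip(cx, 0, w - 1))
            cy = vrng.uniform(rpe_bottom[col], csi[col])
            ry = vrng.uniform(2.0, 5.0)
            rx = vrng.uniform(3.0, 8.0)
            inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            img[inside & choroid] = spec.vessel_intensity

    if spec.speckle_sigma > 0:
        srng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        if spec.speckle_model == "gaussian":
            img = img * (1.0 + srng.normal(0.0, spec.speckle_sigma, (h, w)))
        else:
            shape = 1.0 / spec.speckle_sigma ** 2
            img = img * srng.gamma(shape, 1.0 / shape, (h, w))
    img = np.clip(img, 0.0, 1.0)

    mask = _mask_from_curves(spec, rpe_bottom, csi)
    return img, mask


def _apportion(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` among groups."""
    quotas = counts * total / counts.sum()
    base = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - base), kind="stable")
    for j in order[: total - base.sum()]:
        base[j] += 1
    return base


def _stratified_split(tags, rng: np.random.Generator):
    """8:1:1 split indices, stratified by tag within rounding.

    Split sizes are fixed at the dataset level (val = test = 10%, at least
    one image each) and apportioned across tags by largest remainder, so the
    overall 8:1:1 ratio is exact even when a tag is too rare to appear in
    every split."""
    tags = np.asarray(tags)
    n = len(tags)
    n_test = max(1, int(round(0.1 * n)))
    n_val = max(1, int(round(0.1 * n)))
    if n_test + n_val >= n:
        raise ValueError("too few images for an 8:1:1 split")
    uniq, counts = np.unique(tags, return_counts=True)
    pools = {
        tag: list(np.flatnonzero(tags == tag)[rng.permutation(c)])
        for tag, c in zip(uniq, counts)
    }
    split = np.full(n, "train", dtype=object)
    for part, size in (("test", n_test), ("val", n_val)):
        for tag, take in zip(uniq, _apportion(counts, size)):
            for idx in pools[tag][:take]:
                split[idx] = part
            pools[tag] = pools[tag][take:]
    return list(split)


def generate_arrays(spec: SyntheticSpec, n: int, seed: int,
                    lesioned_fraction: float = 0.32):
    """In-memory dataset: (images, masks, tags, splits), deterministic in seed.

    The default lesioned fraction mirrors a roughly two-thirds/one-third
    normal-to-pathology case mix.
    """
    if n < 10:
        raise ValueError("need n >= 10 for an 8:1:1 split")
    n_lesioned = int(round(lesioned_fraction * n))
    specs = [spec.lesioned() if i < n_lesioned else spec for i in range(n)]
    tags = [s.condition_tag for s in specs]
    seeds = (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)).astype(int)
    pairs = [generate_bscan(s, int(si)) for s, si in zip(specs, seeds)]
    images = [p[0] for p in pairs]
    masks = [p[1] for p in pairs]
    splits = _stratified_split(tags, np.random.default_rng(np.random.SeedSequence([seed, 3])))
    return images, masks, tags, splits


def generate_dataset(spec: SyntheticSpec, n: int, seed: int, out_dir,
                     lesioned_fraction: float = 0.32):
    """Write n image/mask PNG pairs plus a manifest CSV; returns the manifest
    as a list of row dicts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks, tags, splits = generate_arrays(spec, n, seed, lesioned_fraction)
    rows = []
    for i, (img, mask, tag, split) in enumerate(zip(images, masks, tags, splits)):
        img_name, mask_name = f"image_{i:04d}.png", f"mask_{i:04d}.png"
        Image.fromarray(np.round(255.0 * img).astype(np.uint8), mode="L").save(
            out_dir / img_name
        )
        Image.fromarray(mask.astype(np.uint8), mode="L").save(out_dir / mask_name)
        rows.append(
            {"image": img_name, "mask": mask_name,
             "condition_tag": tag, "split": split}
        )
    with open(out_dir / "manifest.csv", "w", newline="\n") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image", "mask", "condition_tag", "split"],
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)
    return rows
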