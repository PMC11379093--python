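"""Simulator soundness: boundary geometry, label exactness, determinism and
split bookkeeping."""

import numpy as np
import pytest

from choroidseg import (
    SyntheticSpec,
    generate_arrays,
    generate_bscan,
    generate_dataset,
    sample_boundaries,
)


class TestBoundaries:
    def test_zero_amplitude_gives_flat_lines_at_mean_depths(self):
        spec = SyntheticSpec(boundary_amplitude=0.0)
        ilm, rpe, csi = sample_boundaries(spec, 3)
        assert np.allclose(ilm, spec.vitreous_depth)
        assert np.allclose(rpe, spec.vitreous_depth + spec.retina_thickness
                           + spec.rpe_thickness)
        assert np.allclose(csi, rpe + spec.choroid_thickness)

    def test_same_seed_reproduces_curves(self):
        spec = SyntheticSpec()
        a = sample_boundaries(spec, 11)
        b = sample_boundaries(spec, 11)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca, cb)

    def test_ordering_holds_at_every_column(self):
        spec = SyntheticSpec()
        ilm, rpe, csi = sample_boundaries(spec, 7)
        assert ilm.shape == (256,)
        assert np.all(ilm < rpe) and np.all(rpe < csi)

    def test_crossing_prone_spec_rejected_at_construction(self):
        with pytest.raises(ValueError, match="crossing"):
            SyntheticSpec(boundary_amplitude=40.0, retina_thickness=20.0)

    def test_out_of_frame_curves_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            SyntheticSpec(vitreous_depth=200.0)


class TestBScan:
    def test_degenerate_render_has_exactly_five_intensities(self):
        spec = SyntheticSpec(boundary_amplitude=0.0, speckle_sigma=0.0,
                             vessel_density=0.0)
        img, mask = generate_bscan(spec, 5)
        assert len(np.unique(img)) == 5
        rpe_bottom = spec.vitreous_depth + spec.retina_thickness + spec.rpe_thickness
        csi = rpe_bottom + spec.choroid_thickness
        rows = np.arange(256)
        inside = (rows > rpe_bottom) & (rows <= csi)
        assert np.array_equal(mask[inside], np.ones_like(mask[inside]))
        assert mask[~inside].sum() == 0

    def test_zero_contrast_hides_csi_but_keeps_mask(self):
        base = SyntheticSpec(speckle_sigma=0.0, vessel_density=0.0)
        fuzzy = SyntheticSpec(speckle_sigma=0.0, vessel_density=0.0,
                              csi_contrast=0.0)
        img_b, mask_b = generate_bscan(base, 9)
        img_f, mask_f = generate_bscan(fuzzy, 9)
        assert fuzzy.sclera_intensity == fuzzy.choroid_intensity
        assert np.array_equal(mask_b, mask_f)
        # below the CSI the fuzzy image equals the choroid intensity
        assert np.all(img_f[-5:, :] == fuzzy.choroid_intensity)

    def test_foreground_fraction_matches_closed_form_from_curves(self):
        spec = SyntheticSpec()
        _, rpe, csi = sample_boundaries(spec, 7)
        _, mask = generate_bscan(spec, 7)
        expected = (np.floor(csi) - np.floor(rpe)).sum() / (256 * 256)
        assert mask.mean() == pytest.approx(expected, abs=1e-12)

    def test_mask_independent_of_noise_parameters(self):
        seeds_masks = []
        for sigma, density, model in [(0.0, 0.0, "gaussian"),
                                      (0.2, 0.5, "gaussian"),
                                      (0.1, 0.15, "gamma")]:
            spec = SyntheticSpec(speckle_sigma=sigma, vessel_density=density,
                                 speckle_model=model)
            _, mask = generate_bscan(spec, 21)
            seeds_masks.append(mask)
        assert np.array_equal(seeds_masks[0], seeds_masks[1])
        assert np.array_equal(seeds_masks[0], seeds_masks[2])

    def test_per_column_foreground_is_one_contiguous_run(self):
        _, mask = generate_bscan(SyntheticSpec(), 13)
        for col in mask.T:
            on = np.flatnonzero(col)
            assert on.size > 0
            assert np.array_equal(on, np.arange(on[0], on[-1] + 1))

    def test_foreground_fraction_monotone_in_choroid_thickness(self):
        fracs = []
        for t in (30.0, 50.0, 70.0):
            spec = SyntheticSpec(choroid_thickness=t)
            _, mask = generate_bscan(spec, 3)
            fracs.append(mask.mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_image_bounded_in_unit_interval(self):
        img, _ = generate_bscan(SyntheticSpec(speckle_sigma=0.3), 2)
        assert img.min() >= 0.0 and img.max() <= 1.0


class TestDataset:
    def test_ten_images_split_eight_one_one(self, tmp_path):
        rows = generate_dataset(SyntheticSpec(height=64, width=64), 10, 0, tmp_path)
        splits = [r["split"] for r in rows]
        assert (splits.count("train"), splits.count("val"),
                splits.count("test")) == (8, 1, 1)
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "image_0000.png").exists()

    def test_condition_ratio_preserved_within_rounding(self):
        _, _, tags, splits = generate_arrays(
            SyntheticSpec(height=64, width=64), 100, 1, lesioned_fraction=0.32
        )
        assert tags.count("lesioned") == 32
        for part, expected_n in (("train", 80), ("val", 10), ("test", 10)):
            sel = [t for t, s in zip(tags, splits) if s == part]
            assert len(sel) == expected_n
            frac = sel.count("lesioned") / len(sel)
            assert abs(frac - 0.32) <= 0.5 / min(10, len(sel)) + 0.02

    def test_same_seed_gives_byte_identical_manifest(self, tmp_path):
        spec = SyntheticSpec(height=64, width=64)
        generate_dataset(spec, 12, 5, tmp_path / "a")
        generate_dataset(spec, 12, 5, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()
        assert (tmp_path / "a" / "image_0003.png").read_bytes() == \
            (tmp_path / "b" / "image_0003.png").read_bytes()

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError, match="8:1:1|n >= 10"):
            generate_arrays(SyntheticSpec(), 5, 0)

    def test_masks_written_with_binary_labels(self, tmp_path):
        from PIL import Image

        generate_dataset(SyntheticSpec(height=64, width=64), 10, 2, tmp_path)
        mask = np.asarray(Image.open(tmp_path / "mask_0000.png"))
        assert set(np.unique(mask)) <= {0, 1}

    def test_roundtrip_through_loader(self, tmp_path):
        from choroidseg import load_dataset

        spec = SyntheticSpec(height=64, width=64)
        generate_dataset(spec, 10, 3, tmp_path)
        ds = load_dataset(tmp_path)
        assert len(ds) == 10
        assert ds.images[0].shape == (64, 64)
        assert ds.images[0].min() >= 0.0 and ds.images[0].max() <= 1.0
        assert set(np.unique(ds.masks[0])) <= {0, 1}
        assert sorted(set(ds.splits)) == ["test", "train", "val"]
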