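import json

import numpy as np
import pytest
from PIL import Image

from sdasnet import (AugmentConfig, Sample, augment_expand, labelme_to_mask,
                     load_dataset, save_dataset)


def square_annotation(x0, y0, x1, y1, label="antler"):
    return {"shapes": [{"label": label,
                        "points": [[x0, y0], [x1, y0], [x1, y1], [x0, y1]]}]}


def square_pixel_count(x0, y0, x1, y1, h, w):
    """Independent count of boundary-inclusive interior pixel centres."""
    n = 0
    for r in range(h):
        for c in range(w):
            if x0 <= c <= x1 and y0 <= r <= y1:
                n += 1
    return n


def make_sample(size=32, fg=16, ident="s0"):
    mask = np.zeros((size, size), dtype=np.uint8)
    lo = (size - fg) // 2
    mask[lo:lo + fg, lo:lo + fg] = 255
    image = np.stack([mask] * 3, axis=-1)
    return Sample(image, mask, id=ident)


class TestSample:
    def test_valid_sample(self):
        s = make_sample()
        assert s.provenance == "original"

    @pytest.mark.parametrize("image,mask", [
        (np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8)),
        (np.zeros((4, 4, 3), np.uint8), np.zeros((4, 5), np.uint8)),
        (np.zeros((4, 4, 3), np.uint8), np.full((4, 4), 7, np.uint8)),
    ])
    def test_invalid_shapes_or_values_rejected(self, image, mask):
        with pytest.raises(ValueError):
            Sample(image, mask, id="bad")

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError):
            Sample(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4), np.uint8),
                   id="bad", provenance="mystery")


class TestLabelme:
    def test_no_shapes_gives_empty_mask(self):
        mask = labelme_to_mask({"shapes": []}, (8, 8))
        np.testing.assert_array_equal(mask, 0)

    def test_square_worked_example(self):
        """(0,0)-(10,10) on 20x20: 11x11 = 121 boundary-inclusive pixels."""
        mask = labelme_to_mask(square_annotation(0, 0, 10, 10), (20, 20))
        assert int((mask == 255).sum()) == 121
        assert mask[10, 10] == 255 and mask[11, 11] == 0

    @pytest.mark.parametrize("rect", [(2, 3, 9, 7), (0, 0, 15, 15), (5, 5, 6, 6)])
    def test_squares_match_analytic_count(self, rect):
        h = w = 16
        mask = labelme_to_mask(square_annotation(*rect), (h, w))
        assert int((mask == 255).sum()) == square_pixel_count(*rect, h, w)

    def test_disjoint_polygons_union(self):
        ann = {"shapes": (square_annotation(0, 0, 3, 3)["shapes"]
                          + square_annotation(10, 10, 13, 13)["shapes"])}
        mask = labelme_to_mask(ann, (20, 20))
        assert int((mask == 255).sum()) == 16 + 16

    def test_overlapping_polygons_union_not_sum(self):
        ann = {"shapes": (square_annotation(0, 0, 5, 5)["shapes"]
                          + square_annotation(0, 0, 5, 5)["shapes"])}
        mask = labelme_to_mask(ann, (10, 10))
        assert int((mask == 255).sum()) == 36

    def test_json_string_accepted(self):
        mask = labelme_to_mask(json.dumps(square_annotation(0, 0, 2, 2)), (5, 5))
        assert int((mask == 255).sum()) == 9

    def test_out_of_bounds_vertices_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            mask = labelme_to_mask(square_annotation(-5, -5, 4, 4), (10, 10))
        assert int((mask == 255).sum()) == 25

    @pytest.mark.parametrize("ann", [
        {"no_shapes": []},
        {"shapes": [{"label": "x", "points": [[0, 0], [1, 1]]}]},
    ])
    def test_malformed_annotation_rejected(self, ann):
        with pytest.raises(ValueError):
            labelme_to_mask(ann, (8, 8))


class TestAugment:
    def test_expansion_is_exactly_four_per_original(self):
        out = augment_expand([make_sample(ident="a"), make_sample(ident="b")])
        assert len(out) == 8
        assert [s.provenance for s in out] == \
            ["original", "affine", "photometric", "noise"] * 2
        assert out[1].id == "a_affine" and out[7].id == "b_noise"

    def test_deterministic_given_seed(self):
        a = augment_expand([make_sample()], AugmentConfig(seed=3))
        b = augment_expand([make_sample()], AugmentConfig(seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)
            np.testing.assert_array_equal(x.mask, y.mask)

    def test_different_seeds_differ(self):
        a = augment_expand([make_sample()], AugmentConfig(seed=3))
        b = augment_expand([make_sample()], AugmentConfig(seed=4))
        assert any(np.any(x.image != y.image) for x, y in zip(a[1:], b[1:]))

    def test_photometric_and_noise_leave_mask_untouched(self):
        sample = make_sample()
        out = augment_expand([sample])
        np.testing.assert_array_equal(out[2].mask, sample.mask)
        np.testing.assert_array_equal(out[3].mask, sample.mask)

    def test_affine_masks_stay_binary(self):
        for seed in range(5):
            out = augment_expand([make_sample()], AugmentConfig(seed=seed))
            assert set(np.unique(out[1].mask)) <= {0, 255}

    def test_affine_transforms_image_and_mask_consistently(self):
        """The image channels encode the mask, so after the shared affine the
        bright image region must still coincide with the mask foreground
        (up to interpolation differences at the boundary)."""
        out = augment_expand([make_sample(size=64, fg=32)],
                             AugmentConfig(seed=1))
        aff = out[1]
        bright = aff.image[..., 0] > 127
        fg = aff.mask == 255
        mismatch = np.mean(bright ^ fg)
        assert mismatch < 0.02

    def test_affine_area_within_scale_bounds(self):
        """Foreground fully inside the canvas: the affine is area-preserving
        up to the scale jitter (0.9..1.1 per axis)."""
        sample = make_sample(size=96, fg=24)
        area = (sample.mask == 255).sum()
        for seed in range(5):
            out = augment_expand([sample], AugmentConfig(seed=seed))
            ratio = (out[1].mask == 255).sum() / area
            assert 0.9 ** 2 * 0.9 < ratio < 1.1 ** 2 * 1.1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_expand([])


class TestDatasetIO:
    def test_save_load_roundtrip(self, tmp_path):
        samples = [make_sample(ident=f"s{i}") for i in range(3)]
        save_dataset(samples, tmp_path, "train")
        loaded = load_dataset(tmp_path, "train")
        assert [s.id for s in loaded] == ["s0", "s1", "s2"]
        for orig, back in zip(samples, loaded):
            np.testing.assert_array_equal(back.image, orig.image)
            np.testing.assert_array_equal(back.mask, orig.mask)

    def test_grayscale_masks_binarised(self, tmp_path):
        base = tmp_path / "train"
        (base / "images").mkdir(parents=True)
        (base / "masks").mkdir(parents=True)
        Image.fromarray(np.zeros((8, 8, 3), np.uint8)).save(
            base / "images" / "x.png")
        gray = np.full((8, 8), 100, np.uint8)
        gray[:4] = 200
        Image.fromarray(gray).save(base / "masks" / "x.png")
        (sample,) = load_dataset(tmp_path, "train")
        np.testing.assert_array_equal(np.unique(sample.mask), [0, 255])
        assert (sample.mask[:4] == 255).all() and (sample.mask[4:] == 0).all()

    def test_resize_on_load(self, tmp_path):
        save_dataset([make_sample(size=32)], tmp_path, "val")
        (sample,) = load_dataset(tmp_path, "val", image_size=(16, 16))
        assert sample.image.shape == (16, 16, 3)
        assert sample.mask.shape == (16, 16)
        assert set(np.unique(sample.mask)) <= {0, 255}

    def test_unpaired_files_rejected(self, tmp_path):
        save_dataset([make_sample(ident="a")], tmp_path, "train")
        Image.fromarray(np.zeros((4, 4, 3), np.uint8)).save(
            tmp_path / "train" / "images" / "orphan.png")
        with pytest.raises(ValueError, match="orphan"):
            load_dataset(tmp_path, "train")

    def test_missing_directories_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(tmp_path, "train")
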