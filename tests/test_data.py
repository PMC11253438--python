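"""Dataset plumbing: tiling, size strata, split, augmentation, resizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paddydetr.data import (
    AnnotatedImage,
    BoxAnnotation,
    SizeClass,
    augment_fourfold,
    classify_size,
    resize_to_model,
    split_dataset,
    tile_image,
)


def blank_image(h, w, anns=(), **kw):
    return AnnotatedImage(pixels=np.zeros((h, w, 3), dtype=np.uint8), annotations=list(anns), **kw)


class TestTypes:
    def test_annotation_area(self):
        ann = BoxAnnotation("field_ridge", (10, 10, 42, 42))
        assert ann.area == 1024

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            BoxAnnotation("dandelion", (0, 0, 1, 1))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoxAnnotation("field_ridge", (5, 5, 5, 10))

    def test_annotation_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            blank_image(50, 50, [BoxAnnotation("field_ridge", (10, 10, 60, 20))])


class TestClassifySize:
    @pytest.mark.parametrize(
        "area,expected",
        [
            (1024, SizeClass.SMALL),  # exactly 32^2 -> small
            (1025, SizeClass.MEDIUM),
            (9216, SizeClass.MEDIUM),  # exactly 96^2 -> medium
            (9217, SizeClass.LARGE),
            (1, SizeClass.SMALL),
        ],
    )
    def test_boundaries(self, area, expected):
        assert classify_size(float(area)) is expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            classify_size(0.0)

    def test_partition_fires_exactly_once(self, rng):
        areas = rng.uniform(0.1, 20000, size=10_000)
        for a in areas:
            memberships = [a <= 32**2, 32**2 < a <= 96**2, a > 96**2]
            assert sum(memberships) == 1
            expected = [SizeClass.SMALL, SizeClass.MEDIUM, SizeClass.LARGE][memberships.index(True)]
            assert classify_size(a) is expected


class TestTiling:
    def test_exact_grid(self):
        tiles = tile_image(blank_image(1200, 1200), 600)
        assert len(tiles) == 4
        assert {t.tile_origin for t in tiles} == {(0, 0), (0, 600), (600, 0), (600, 600)}

    def test_identity_case(self):
        img = blank_image(600, 600, [BoxAnnotation("field_ridge", (10, 10, 100, 100))])
        (tile,) = tile_image(img, 600)
        np.testing.assert_array_equal(tile.pixels, img.pixels)
        assert tile.annotations[0].box == img.annotations[0].box

    def test_remainders_dropped(self):
        tiles = tile_image(blank_image(700, 1250), 600)
        assert len(tiles) == 2  # 2 cols x 1 row; 50 px and 100 px strips dropped

    def test_oversized_tile_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no tiles"):
            assert tile_image(blank_image(100, 100), 600) == []

    def test_annotation_clipped_and_reassigned(self):
        ann = BoxAnnotation("patch_barnyard_grass", (550, 100, 700, 300))
        tiles = tile_image(blank_image(600, 1200, [ann]), 600)
        left, right = tiles
        assert left.annotations[0].box == (550, 100, 600, 300)
        assert right.annotations[0].box == (0, 100, 100, 300)

    def test_sliver_annotations_discarded(self):
        # 2 px survive in the right tile: below the 4 px minimum side
        ann = BoxAnnotation("single_barnyard_grass", (560, 100, 602, 150))
        tiles = tile_image(blank_image(600, 1200, [ann]), 600)
        assert len(tiles[0].annotations) == 1
        assert len(tiles[1].annotations) == 0

    @given(
        h=st.integers(1, 1500),
        w=st.integers(1, 1500),
        tile=st.integers(1, 700),
    )
    @settings(max_examples=40, deadline=None)
    def test_pixel_coverage_accounting(self, h, w, tile):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tiles = tile_image(blank_image(h, w), tile)
        assert len(tiles) == (h // tile) * (w // tile)
        covered = sum(t.pixels.shape[0] * t.pixels.shape[1] for t in tiles)
        assert covered == (h // tile) * (w // tile) * tile * tile
        origins = {t.tile_origin for t in tiles}
        assert len(origins) == len(tiles)  # no overlaps: origins on a disjoint grid


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(100, (70, 20, 10)), (10, (7, 2, 1)), (12, (9, 2, 1))])
    def test_sizes_follow_ratio_with_remainder_to_train(self, n, expected):
        split = split_dataset(list(range(n)), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == expected

    def test_disjoint_and_exhaustive(self):
        items = list(range(53))
        split = split_dataset(items, seed=3)
        combined = split.train + split.val + split.test
        assert sorted(combined) == items
        assert len(set(split.train) & set(split.val)) == 0
        assert len(set(split.val) & set(split.test)) == 0

    def test_seed_determinism_and_shuffling(self):
        a = split_dataset(list(range(30)), seed=5)
        b = split_dataset(list(range(30)), seed=5)
        assert a.train == b.train and a.test == b.test
        c = split_dataset(list(range(30)), seed=6)
        assert a.train != c.train

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], ratios=(7, -2, 1))


class TestResize:
    def test_boxes_scale_with_image(self):
        img = blank_image(600, 600, [BoxAnnotation("field_ridge", (0, 0, 600, 600))])
        out = resize_to_model(img, 640)
        assert out.pixels.shape == (640, 640, 3)
        assert out.annotations[0].box == (0, 0, 640, 640)

    def test_identity_when_already_sized(self):
        img = blank_image(640, 640)
        assert resize_to_model(img, 640) is img

    def test_bilinear_preserves_constant_images(self):
        img = AnnotatedImage(pixels=np.full((600, 600, 3), 77, dtype=np.uint8))
        out = resize_to_model(img, 640)
        assert (out.pixels == 77).all()


class TestAugment:
    @pytest.mark.parametrize("n_in,n_out", [(438, 1752), (218, 872), (2876, 11504), (0, 0)])
    def test_fourfold_counts(self, n_in, n_out):
        samples = [blank_image(8, 8) for _ in range(n_in)]
        assert len(augment_fourfold(samples, seed=0)) == n_out

    def test_total_dataset_expansion(self):
        """The three class subsets together expand 3532 -> 14128."""
        out = augment_fourfold([blank_image(8, 8) for _ in range(438 + 218 + 2876)], seed=1)
        assert len(out) == 14_128

    def test_seed_determinism(self, small_scenes):
        a = augment_fourfold(small_scenes[:2], seed=9)
        b = augment_fourfold(small_scenes[:2], seed=9)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia.pixels, ib.pixels)
            assert [x.box for x in ia.annotations] == [x.box for x in ib.annotations]

    def test_originals_preserved_first_in_each_quadruple(self, small_scenes):
        out = augment_fourfold(small_scenes[:2], seed=0)
        np.testing.assert_array_equal(out[0].pixels, small_scenes[0].pixels)
        np.testing.assert_array_equal(out[4].pixels, small_scenes[1].pixels)

    def test_rotation_remaps_boxes_consistently(self, small_scenes):
        from paddydetr.data import _rotate90

        img = small_scenes[0]
        rot = _rotate90(img, 1)
        back = _rotate90(rot, 3)
        np.testing.assert_array_equal(back.pixels, img.pixels)
        for a, b in zip(img.annotations, back.annotations):
            np.testing.assert_allclose(a.box, b.box, atol=1e-9)

    def test_transformed_boxes_stay_inside_image(self, small_scenes):
        for aug in augment_fourfold(small_scenes[:3], seed=2):
            h, w = aug.pixels.shape[:2]
            for ann in aug.annotations:
                x1, y1, x2, y2 = ann.box
                assert 0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h
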