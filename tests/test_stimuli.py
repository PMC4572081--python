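"""Synthetic stimulus generators: determinism, structure, scrambling."""

import numpy as np
import pytest
from PIL import Image

from tracenet.stimuli import (
    StimulusSet,
    gen_catastrophic_pair,
    gen_class_exemplars,
    gen_part_configured_objects,
    gen_part_scramble,
    gen_translation_view_grid,
    gen_view_series,
    load_image_dir,
    scramble_quadrants,
)


@pytest.mark.parametrize(
    "gen",
    [
        lambda r: gen_class_exemplars(3, 4, r),
        lambda r: gen_view_series(2, 6, 60.0, r),
        lambda r: gen_part_configured_objects(4, 3, r),
        lambda r: gen_catastrophic_pair(r),
        lambda r: gen_translation_view_grid(2, 2, 3, r, spacing=3),
    ],
)
def test_generators_are_pure_functions_of_seed(gen):
    a = gen(np.random.default_rng(11))
    b = gen(np.random.default_rng(11))
    np.testing.assert_array_equal(a.images, b.images)
    np.testing.assert_array_equal(a.object_ids, b.object_ids)
    assert a.transform_ids == b.transform_ids


def test_presentation_order_is_object_contiguous():
    ss = gen_class_exemplars(4, 5, np.random.default_rng(0))
    objs = ss.object_ids[ss.presentation_order]
    assert ss.n_block_boundaries() == len(ss.unique_objects()) - 1
    # consecutive entries share an object except at block boundaries
    changes = np.flatnonzero(objs[1:] != objs[:-1])
    assert len(changes) == 3


class TestClassExemplars:
    def test_zero_jitter_zero_clutter_gives_identical_exemplars(self):
        ss = gen_class_exemplars(2, 4, np.random.default_rng(1), jitter=0.0, n_clutter=0)
        for c in (0, 1):
            imgs = ss.images[ss.object_ids == c]
            for img in imgs[1:]:
                np.testing.assert_array_equal(img, imgs[0])

    def test_pixel_nearest_neighbour_beats_chance_on_test_split(self):
        """Brute-force pixel classifier as a sanity oracle: the class
        families must be separable at all."""
        ss = gen_class_exemplars(2, 20, np.random.default_rng(2), n_test=6)
        train, test = ss.train_set(), ss.test_set()
        xtr = train.images.reshape(len(train), -1)
        correct = 0
        for img, label in zip(test.images, test.object_ids):
            d = ((xtr - img.ravel()) ** 2).sum(axis=1)
            correct += train.object_ids[d.argmin()] == label
        assert correct / len(test) > 0.5  # chance for 2 classes

    def test_split_sizes_and_disjointness(self):
        ss = gen_class_exemplars(2, 10, np.random.default_rng(3), n_test=4)
        assert (ss.split == "test").sum() == 2 * 4
        assert (ss.split == "train").sum() == 2 * 6


class TestViewSeries:
    def test_adjacent_views_more_similar_than_opposite(self):
        ss = gen_view_series(3, 8, 45.0, np.random.default_rng(4))
        for o in range(3):
            imgs = ss.images[ss.object_ids == o].reshape(8, -1)
            adj = np.corrcoef(imgs[0], imgs[1])[0, 1]
            opp = np.corrcoef(imgs[0], imgs[4])[0, 1]
            assert adj > opp

    def test_full_rotation_no_duplicate_azimuths(self):
        ss = gen_view_series(1, 72, 5.0, np.random.default_rng(5))
        assert len(set(ss.transform_ids)) == 72

    def test_cross_validation_offset_views(self):
        ss = gen_view_series(2, 9, 40.0, np.random.default_rng(6),
                             test_n_views=18, test_spacing=20.0, test_offset=10.0)
        train_az = {float(t[2:7]) for t in ss.transform_ids if not t.endswith("_test")}
        test_az = {float(t[2:7]) for t in ss.transform_ids if t.endswith("_test")}
        assert train_az.isdisjoint(test_az)
        # every test view is exactly 10 degrees from the nearest train view
        for az in test_az:
            dmin = min(min(abs(az - tr), 360 - abs(az - tr)) for tr in train_az)
            assert dmin == pytest.approx(10.0)

    def test_excessive_span_rejected(self):
        with pytest.raises(ValueError):
            gen_view_series(1, 10, 40.0, np.random.default_rng(0))


class TestScramble:
    def test_pixel_multiset_preserved_exactly(self):
        ss = gen_part_configured_objects(2, 2, np.random.default_rng(7))
        scr = gen_part_scramble(ss, 3, np.random.default_rng(8))
        for i, simg in enumerate(scr.images):
            orig = ss.images[i // 3]
            np.testing.assert_array_equal(np.sort(simg.ravel()), np.sort(orig.ravel()))

    def test_identity_never_emitted_and_all_quadrants_displaced(self):
        ss = gen_part_configured_objects(2, 2, np.random.default_rng(9))
        scr = gen_part_scramble(ss, 5, np.random.default_rng(10))
        for perm in scr.metadata["permutations"]:
            assert tuple(perm) != (0, 1, 2, 3)
            assert all(perm[i] != i for i in range(4))  # derangements by default

    def test_inverse_permutation_restores_original(self, rng):
        img = rng.uniform(size=(16, 16)).astype(np.float32)
        perm = (2, 3, 1, 0)
        inv = tuple(np.argsort(perm))
        np.testing.assert_array_equal(
            scramble_quadrants(scramble_quadrants(img, perm), inv), img
        )

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError):
            scramble_quadrants(np.zeros((15, 16)), (1, 0, 3, 2))


class TestCatastrophicPair:
    def test_design_shape(self):
        ss = gen_catastrophic_pair(np.random.default_rng(12))
        assert len(ss) == 8
        assert sorted(ss.unique_objects().tolist()) == [0, 1]
        assert all((ss.object_ids == o).sum() == 4 for o in (0, 1))

    def test_interior_views_resemble_each_other_most(self):
        """The two interior-feature views share the revealed pattern, so
        they correlate more with each other than with their own object's
        other views (computed from the full 8x8 correlation matrix)."""
        ss = gen_catastrophic_pair(np.random.default_rng(13))
        flat = ss.images.reshape(8, -1)
        corr = np.corrcoef(flat)
        r0, r1 = ss.metadata["reveal_views"]
        i0, i1 = r0, 4 + r1
        cross = corr[i0, i1]
        own0 = [corr[i0, v] for v in range(4) if v != i0]
        own1 = [corr[i1, v] for v in range(4, 8) if v != i1]
        assert cross > max(own0) and cross > max(own1)

    def test_views_of_an_object_share_an_outline(self):
        ss = gen_catastrophic_pair(np.random.default_rng(14))
        for o in (0, 1):
            imgs = ss.images[ss.object_ids == o]
            masks = [img != np.float32(0.5) for img in imgs]
            # outline pixels (outside the interior) agree across views
            union = np.logical_or.reduce(masks)
            inter = np.logical_and.reduce(masks)
            assert inter.sum() / union.sum() > 0.5


class TestTranslationGrid:
    def test_default_transform_count_is_100_per_object(self):
        ss = gen_translation_view_grid(1, 4, 5, np.random.default_rng(15), spacing=2)
        assert (ss.object_ids == 0).sum() == 4 * 25

    def test_zero_offset_equals_base_view(self):
        ss = gen_translation_view_grid(1, 1, [(0, 0), (3, -2)],
                                       np.random.default_rng(16))
        base = ss.images[[t.endswith("loc+0+0") for t in ss.transform_ids]][0]
        shifted = ss.images[[t.endswith("loc+3-2") for t in ss.transform_ids]][0]
        assert not np.array_equal(base, shifted)
        # shifting back restores the base exactly (integer translation)
        from tracenet.stimuli import _shift_int

        np.testing.assert_array_equal(_shift_int(shifted, -3, 2)[4:-4, 4:-4],
                                      base[4:-4, 4:-4])

    def test_oversized_offsets_rejected(self):
        with pytest.raises(ValueError):
            gen_translation_view_grid(1, 1, [(40, 0)], np.random.default_rng(0))


class TestLoadImageDir:
    def test_roundtrip_through_png(self, tmp_path):
        ss = gen_class_exemplars(2, 3, np.random.default_rng(17))
        ss.save(tmp_path)
        back = load_image_dir(tmp_path, target_dims=ss.dims)
        assert len(back) == len(ss)
        assert np.abs(back.images - ss.images).max() <= 1.0 / 255 + 1e-6

    def test_colour_converted_with_luma_weights(self, tmp_path):
        d = tmp_path / "obj0"
        d.mkdir()
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        rgb[..., 0] = 200  # pure red
        Image.fromarray(rgb).save(d / "t0.png")
        ss = load_image_dir(tmp_path, target_dims=(10, 10))
        assert ss.images[0, 5, 5] == pytest.approx(0.299 * 200 / 255, abs=0.005)

    def test_mixed_sizes_resampled_to_target(self, tmp_path):
        for o, size in enumerate([(20, 30), (64, 64)]):
            d = tmp_path / f"obj{o}"
            d.mkdir()
            Image.fromarray(np.full(size, 128, dtype=np.uint8)).save(d / "a.png")
        ss = load_image_dir(tmp_path, target_dims=(16, 16))
        assert ss.images.shape == (2, 16, 16)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            load_image_dir(tmp_path)
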