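"""Size classes, the green-purity rule, dataset building and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tilecover.dataset import (
    AugmentationConfig,
    GreenRule,
    SizeClass,
    SourceImage,
    augment_stream,
    build_dataset,
    classify_size,
    purity_fraction,
)
from tilecover.errors import DatasetError
from tilecover.tiling import ChopConfig

from conftest import MID_GREEN, PURE_YELLOW, uniform_image


class TestSizeClass:
    @pytest.mark.parametrize(
        "length,expected",
        [(10, "S"), (50, "S"), (51, "M"), (75, "M"), (100, "M"),
         (101, "L"), (300, "L"), (9, "OUT_OF_RANGE"), (301, "OUT_OF_RANGE")],
    )
    def test_boundaries(self, length, expected):
        assert classify_size(length) == SizeClass(expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_size(0)

    def test_classes_partition_the_full_range(self):
        # every reference length in [10, 300] belongs to exactly one class
        for length in range(10, 301):
            assert classify_size(length) in (SizeClass.S, SizeClass.M, SizeClass.L)
        assert {classify_size(n) for n in range(10, 51)} == {SizeClass.S}
        assert {classify_size(n) for n in range(51, 101)} == {SizeClass.M}
        assert {classify_size(n) for n in range(101, 301)} == {SizeClass.L}


class TestPurityRule:
    def test_pure_yellow_has_no_foliage(self):
        assert purity_fraction(uniform_image(30, 30, PURE_YELLOW)) == 0.0

    def test_mid_green_is_all_foliage(self):
        assert purity_fraction(uniform_image(30, 30, MID_GREEN)) == 1.0

    def test_half_and_half_counts_exactly(self):
        tile = uniform_image(30, 30, PURE_YELLOW)
        tile[:15] = MID_GREEN
        rule = GreenRule()
        # brute-force pixel count under the same predicate
        expected = rule.mask(tile).sum() / tile[..., 0].size
        assert purity_fraction(tile, rule) == expected == 0.5

    def test_rule_is_configurable(self):
        tile = uniform_image(10, 10, MID_GREEN)
        narrow = GreenRule(hue_min_deg=150.0, hue_max_deg=170.0)
        assert purity_fraction(tile, narrow) == 0.0


def _sources(color, n, size_class=None, hw=60):
    return [SourceImage(image=uniform_image(hw, hw, color), source_id=f"s{i}",
                        size_class=size_class) for i in range(n)]


class TestBuildDataset:
    def test_pure_sources_keep_all_tiles(self):
        ds = build_dataset(_sources(PURE_YELLOW, 1), _sources(MID_GREEN, 1),
                           ChopConfig(), seed=0)
        assert len(ds) == 18
        assert int(ds.labels.sum()) == 9

    def test_green_positives_are_filtered_out(self):
        tile = uniform_image(60, 60, PURE_YELLOW)
        tile[:, ::2] = MID_GREEN  # 50 % green everywhere
        with pytest.raises(DatasetError, match="positive"):
            build_dataset([SourceImage(tile, "p0")], _sources(MID_GREEN, 1), ChopConfig())

    def test_mix_sizes_keeps_all_size_classes(self):
        pos = (_sources((230, 210, 40), 2, SizeClass.S)
               + _sources((230, 210, 40), 2, SizeClass.M)
               + _sources((230, 210, 40), 2, SizeClass.L))
        ds = build_dataset(pos, _sources(MID_GREEN, 2), ChopConfig(),
                           mix_sizes=True, seed=1, max_tiles_per_class=12)
        present = {s for s in ds.size_classes if s is not None}
        assert present == {SizeClass.S, SizeClass.M, SizeClass.L}
        assert int(ds.labels.sum()) <= 12

    def test_raising_threshold_never_loses_positives(self, rng):
        # tiles with varying green fractions; retention is monotone in threshold
        pos_img = np.empty((60, 60, 3), dtype=np.uint8)
        pos_img[:] = PURE_YELLOW
        green_mask = rng.random((60, 60)) < 0.25
        pos_img[green_mask] = MID_GREEN
        counts = []
        for threshold in (0.1, 0.2, 0.3, 0.5, 1.0):
            try:
                ds = build_dataset([SourceImage(pos_img, "p")], _sources(MID_GREEN, 1),
                                   ChopConfig(), purity_threshold=threshold, seed=0)
                counts.append(int(ds.labels.sum()))
            except DatasetError:
                counts.append(0)  # everything filtered at a strict threshold
        assert counts == sorted(counts)
        assert counts[-1] == 9  # threshold 1.0 retains every tile

    def test_split_is_disjoint_and_stratified(self):
        ds = build_dataset(_sources(PURE_YELLOW, 2), _sources(MID_GREEN, 2),
                           ChopConfig(), seed=3)
        assert set(ds.split) == {"train", "validation"}
        assert len(ds.train) + len(ds.validation) == len(ds)
        assert 0 < ds.validation.labels.mean() < 1  # both classes held out


class TestAugmentation:
    def test_identity_config_only_rescales(self, separable_tile_set):
        config = AugmentationConfig(width_shift_range=0, height_shift_range=0,
                                    horizontal_flip=False, zoom_range=0)
        stream = augment_stream(separable_tile_set, config, seed=5)
        ref = separable_tile_set.tiles.astype(np.float32) / 255.0
        for _ in range(10):
            tile, label = next(stream)
            matches = np.isclose(ref, tile[None][0]).all(axis=(1, 2, 3))
            assert matches.any()
            assert label in (0, 1)

    def test_outputs_stay_in_unit_range(self, separable_tile_set):
        stream = augment_stream(separable_tile_set, AugmentationConfig(), seed=6)
        for _ in range(25):
            tile, _ = next(stream)
            assert tile.min() >= 0.0 and tile.max() <= 1.0
            assert tile.shape == (30, 30, 3)

    def test_same_seed_reproduces_stream(self, separable_tile_set):
        a = augment_stream(separable_tile_set, AugmentationConfig(), seed=9)
        b = augment_stream(separable_tile_set, AugmentationConfig(), seed=9)
        for _ in range(50):
            ta, la = next(a)
            tb, lb = next(b)
            assert la == lb
            np.testing.assert_array_equal(ta, tb)

    def test_labels_follow_source_tiles(self, separable_tile_set):
        # a yellow-looking augmented tile must carry the yellow label
        stream = augment_stream(separable_tile_set, AugmentationConfig(), seed=11)
        for _ in range(50):
            tile, label = next(stream)
            is_yellow = tile[..., 0].mean() - tile[..., 2].mean() > 0.2
            assert label == int(is_yellow)

    @given(st.floats(min_value=-0.5, max_value=1.5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invalid_ranges_rejected(self, value):
        if 0.0 <= value < 1.0:
            AugmentationConfig(zoom_range=value)
        else:
            with pytest.raises(ValueError):
                AugmentationConfig(zoom_range=value)
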