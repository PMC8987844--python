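"""Cell-level fusion of overlapping tile predictions and overlay rendering."""

import numpy as np
import pytest

from tilecover.io import load_image, save_image
from tilecover.overlay import (
    aggregate_cells,
    calibrate_cell_threshold,
    estimate_cover,
    render_overlay,
)
from tilecover.synth import SceneSpec, make_corpus
from tilecover.tiling import ChopConfig, make_grid


class YellowFractionModel:
    """Stand-in classifier: per-tile probability = warm-yellow pixel fraction."""

    def predict_proba(self, tiles):
        tiles = np.asarray(tiles, dtype=np.float64)
        yellow = (tiles[..., 0] > 150) & (tiles[..., 2] < 110)
        return yellow.mean(axis=(1, 2))


def brute_force_cell_means(grid, probs):
    """Independent per-cell average over all tiles covering each cell."""
    s, t = grid.stride_px, grid.tile_size_px
    rows = ((grid.n_rows - 1) * s + t) // s
    cols = ((grid.n_cols - 1) * s + t) // s
    probs = np.asarray(probs, dtype=float).reshape(grid.n_rows, grid.n_cols)
    out = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            covering = []
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    y0, x0 = r * s, c * s
                    if y0 <= i * s and (i + 1) * s <= y0 + t and x0 <= j * s and (j + 1) * s <= x0 + t:
                        covering.append(probs[r, c])
            out[i, j] = np.mean(covering)
    return out


class TestAggregation:
    def test_all_positive_probabilities(self):
        grid = make_grid(90, 90, ChopConfig())
        cov = aggregate_cells(grid, np.ones(grid.n_tiles))
        assert cov.positive_fraction == 1.0
        assert cov.cell_call.all()

    def test_no_overlap_cells_inherit_their_tile(self, rng):
        grid = make_grid(90, 90, ChopConfig(tile_size_px=30, overlap_fraction=0.0))
        probs = rng.random(grid.n_tiles)
        cov = aggregate_cells(grid, probs)
        np.testing.assert_allclose(cov.cell_probability.ravel(), probs)

    def test_single_positive_tile_matches_brute_force(self):
        grid = make_grid(60, 60, ChopConfig())  # 3x3 tiles
        probs = np.zeros(9)
        probs[4] = 1.0  # centre tile
        cov = aggregate_cells(grid, probs)
        expected = brute_force_cell_means(grid, probs)
        np.testing.assert_allclose(cov.cell_probability, expected)
        np.testing.assert_array_equal(cov.cell_call, expected >= 0.5)

    def test_random_grids_match_brute_force(self, rng):
        for _ in range(5):
            h = int(rng.integers(30, 120))
            w = int(rng.integers(30, 120))
            grid = make_grid(w, h, ChopConfig())
            if grid.n_tiles == 0:
                continue
            probs = rng.random(grid.n_tiles)
            cov = aggregate_cells(grid, probs)
            np.testing.assert_allclose(cov.cell_probability,
                                       brute_force_cell_means(grid, probs))

    def test_positive_fraction_monotone_in_positive_tiles(self):
        grid = make_grid(75, 75, ChopConfig())
        probs = np.zeros(grid.n_tiles)
        previous = -1.0
        for k in range(grid.n_tiles + 1):
            cov = aggregate_cells(grid, probs)
            assert cov.positive_fraction >= previous
            previous = cov.positive_fraction
            if k < grid.n_tiles:
                probs[k] = 1.0

    def test_count_mismatch_rejected(self):
        grid = make_grid(60, 60, ChopConfig())
        with pytest.raises(ValueError):
            aggregate_cells(grid, np.ones(5))


class TestCoverCalibration:
    def test_threshold_comes_from_grid_and_reduces_calibration_error(self):
        chop = ChopConfig()
        model = YellowFractionModel()
        scenes, _ = make_corpus(3, SceneSpec(width=100, height=100),
                                cover_range=(0.2, 0.7), seed=17)
        threshold = calibrate_cell_threshold(model, scenes, chop)
        assert 0.5 <= threshold <= 0.8

        def mae(thr):
            return np.mean([
                abs(estimate_cover(model, s.image, chop, threshold=thr).positive_fraction
                    - s.cover_fraction)
                for s in scenes
            ])

        assert mae(threshold) <= mae(0.5) + 1e-12

    def test_estimate_cover_equals_manual_pipeline(self):
        from tilecover.tiling import chop_image

        chop = ChopConfig()
        model = YellowFractionModel()
        scene, = make_corpus(1, SceneSpec(width=100, height=100),
                             cover_range=(0.4, 0.4), seed=23)[0]
        cov = estimate_cover(model, scene.image, chop)
        grid, tiles = chop_image(scene.image, chop)
        manual = aggregate_cells(grid, model.predict_proba(
            np.stack([t.pixels for t in tiles])))
        np.testing.assert_array_equal(cov.cell_call, manual.cell_call)
        assert cov.positive_fraction == manual.positive_fraction


class TestRendering:
    def _coverage(self, rng, h=60, w=60):
        grid = make_grid(w, h, ChopConfig())
        return grid, aggregate_cells(grid, rng.random(grid.n_tiles))

    def test_alpha_zero_returns_input(self, rng):
        grid, cov = self._coverage(rng)
        image = rng.integers(0, 256, (60, 60, 3), dtype=np.uint8)
        np.testing.assert_array_equal(render_overlay(image, cov, alpha=0.0), image)

    def test_alpha_one_paints_pure_red_on_positive_cells(self, rng):
        grid = make_grid(60, 60, ChopConfig())
        cov = aggregate_cells(grid, np.ones(grid.n_tiles))
        image = rng.integers(0, 256, (60, 60, 3), dtype=np.uint8)
        out = render_overlay(image, cov, alpha=1.0)
        s = grid.stride_px
        covered = cov.cell_call.shape[0] * s
        assert (out[:covered, :covered] == (255, 0, 0)).all()

    def test_dimension_mismatch_rejected(self, rng):
        grid, cov = self._coverage(rng)
        with pytest.raises(ValueError):
            render_overlay(np.zeros((30, 30, 3), dtype=np.uint8), cov)

    def test_png_round_trip_preserves_cell_colors(self, rng, tmp_path):
        grid = make_grid(60, 60, ChopConfig())
        probs = np.zeros(grid.n_tiles)
        probs[0] = 1.0
        cov = aggregate_cells(grid, probs)
        image = rng.integers(0, 256, (60, 60, 3), dtype=np.uint8)
        out = render_overlay(image, cov, alpha=1.0)
        save_image(tmp_path / "overlay.png", out)
        back = load_image(tmp_path / "overlay.png")
        assert back.shape == image.shape
        s = grid.stride_px
        for i in range(cov.cell_call.shape[0]):
            for j in range(cov.cell_call.shape[1]):
                centre = back[i * s + s // 2, j * s + s // 2]
                expected = (255, 0, 0) if cov.cell_call[i, j] else (0, 255, 0)
                assert tuple(centre) == expected
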