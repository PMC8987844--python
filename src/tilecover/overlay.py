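"""Mosaic overlays and coverage estimation from per-tile predictions.

With 50 % overlap each stride-sized cell of the image is covered by up to
four tiles.  Overlapping predictions are fused per cell by averaging the
probabilities of every tile whose footprint fully contains the cell and
thresholding the mean at 0.5.  The fraction of positive cells estimates
the target's cover in the image; the overlay tints positive cells red and
negative cells green over the source photograph.  Cells right/below the
last complete tile footprint are left untinted.

When the classifier's probabilities saturate, thresholding the cell mean
at 0.5 dilates every detected patch by roughly one cell (a boundary cell
with half its covering tiles confidently positive averages to >= 0.5), so
cover estimates carry a positive bias.  `calibrate_cell_threshold`
removes it by picking the cell threshold that best recovers the known
cover of calibration scenes; 0.5 remains the uncalibrated default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tiling import ChopConfig, TileGrid, chop_image

__all__ = ["CoverageMap", "aggregate_cells", "render_overlay",
           "calibrate_cell_threshold", "estimate_cover"]


@dataclass
class CoverageMap:
    grid: TileGrid
    cell_probability: np.ndarray  # (cell_rows, cell_cols) mean tile probability
    cell_call: np.ndarray  # boolean

    @property
    def n_cells(self) -> int:
        return self.cell_call.size

    @property
    def n_positive(self) -> int:
        return int(self.cell_call.sum())

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_cells if self.n_cells else 0.0

    def summary(self, source_id: str = "") -> dict:
        return {"source_id": source_id, "n_cells": int(self.n_cells),
                "n_positive": self.n_positive,
                "positive_fraction": self.positive_fraction}


def _cell_dims(grid: TileGrid) -> tuple[int, int]:
    s, t = grid.stride_px, grid.tile_size_px
    rows = ((grid.n_rows - 1) * s + t) // s if grid.n_rows else 0
    cols = ((grid.n_cols - 1) * s + t) // s if grid.n_cols else 0
    return rows, cols


def aggregate_cells(grid: TileGrid, tile_probabilities: np.ndarray,
                    threshold: float = 0.5) -> CoverageMap:
    """Fuse per-tile probabilities onto the stride-resolution cell lattice.

    ``tile_probabilities`` holds one probability per grid tile, row-major
    (a flat array of length ``n_tiles`` or an ``(n_rows, n_cols)`` array).
    Each cell averages the probabilities of all tiles whose footprint
    fully contains it; the call is ``mean >= threshold``.
    """
    probs = np.asarray(tile_probabilities, dtype=np.float64)
    if probs.size != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} probabilities, got {probs.size}")
    probs = probs.reshape(grid.n_rows, grid.n_cols)
    s, t = grid.stride_px, grid.tile_size_px
    cell_rows, cell_cols = _cell_dims(grid)
    span = t // s  # cells fully inside one tile along each axis
    acc = np.zeros((cell_rows, cell_cols))
    cnt = np.zeros((cell_rows, cell_cols))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            acc[r : r + span, c : c + span] += probs[r, c]
            cnt[r : r + span, c : c + span] += 1.0
    mean = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return CoverageMap(grid=grid, cell_probability=mean, cell_call=mean >= threshold)


def render_overlay(image: np.ndarray, coverage: CoverageMap, alpha: float = 0.4) -> np.ndarray:
    """Alpha-blend the red/green call mosaic over the source image."""
    image = np.asarray(image)
    if image.shape[:2] != (coverage.grid.image_height_px, coverage.grid.image_width_px):
        raise ValueError(
            f"image {image.shape[:2]} does not match grid "
            f"({coverage.grid.image_height_px}, {coverage.grid.image_width_px})"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    out = image.astype(np.float64).copy()
    s = coverage.grid.stride_px
    red = np.array([255.0, 0.0, 0.0])
    green = np.array([0.0, 255.0, 0.0])
    rows, cols = coverage.cell_call.shape
    for i in range(rows):
        for j in range(cols):
            tint = red if coverage.cell_call[i, j] else green
            ys, xs = i * s, j * s
            out[ys : ys + s, xs : xs + s] = (
                (1.0 - alpha) * out[ys : ys + s, xs : xs + s] + alpha * tint
            )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def estimate_cover(model, image: np.ndarray, chop: ChopConfig | None = None,
                   threshold: float = 0.5) -> CoverageMap:
    """Chop an image, classify its tiles and fuse the calls into cells."""
    chop = chop or ChopConfig()
    grid, tiles = chop_image(image, chop)
    probs = model.predict_proba(np.stack([t.pixels for t in tiles]))
    return aggregate_cells(grid, probs, threshold=threshold)


def calibrate_cell_threshold(
    model,
    calibration_scenes,
    chop: ChopConfig | None = None,
    thresholds: np.ndarray | None = None,
) -> float:
    """Pick the cell threshold that best recovers known scene cover.

    ``calibration_scenes`` are synthetic scenes (with truth masks) held
    apart from any evaluation material; the returned threshold minimises
    the mean absolute error between ``positive_fraction`` and the true
    mask fraction over those scenes.
    """
    chop = chop or ChopConfig()
    if thresholds is None:
        thresholds = np.arange(0.50, 0.801, 0.05)
    pairs = []
    for scene in calibration_scenes:
        grid, tiles = chop_image(scene.image, chop)
        probs = model.predict_proba(np.stack([t.pixels for t in tiles]))
        pairs.append((grid, probs, scene.cover_fraction))
    errors = [
        float(np.mean([abs(aggregate_cells(g, p, threshold=t).positive_fraction - c)
                       for g, p, c in pairs]))
        for t in thresholds
    ]
    return float(thresholds[int(np.argmin(errors))])
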