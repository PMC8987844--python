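"""Chopped-picture tiling: overlapping square tiles and their geometry.

An image is "chopped" into fixed-size square tiles laid out on a regular
grid.  With tile size ``t`` and overlap fraction ``f`` the grid stride is
``t * (1 - f)`` pixels; the default configuration (30-px tiles, 50 %
overlap, stride 15) is the one used throughout the pipeline.  Tiles are
indexed ``(row, col)`` with tile ``(r, c)`` anchored at pixel
``(x, y) = (c * stride, r * stride)``; rows index image height.  Trailing
pixels at the right/bottom edge that cannot form a full tile are dropped,
because the downstream classifier requires fixed-size input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import ConfigurationError

__all__ = ["ChopConfig", "TileGrid", "Tile", "chop_image", "tile_bounds"]


@dataclass(frozen=True)
class ChopConfig:
    """Tiling geometry: tile edge length and fractional overlap.

    ``stride_px`` is derived and must come out to a whole number of
    pixels; 30-px tiles with 50 % overlap give a 15-px stride.
    """

    tile_size_px: int = 30
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.tile_size_px < 2:
            raise ConfigurationError(f"tile_size_px must be >= 2, got {self.tile_size_px}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigurationError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )
        stride = self.tile_size_px * (1.0 - self.overlap_fraction)
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ConfigurationError(
                f"tile_size_px={self.tile_size_px} with overlap_fraction="
                f"{self.overlap_fraction} gives non-integral stride {stride!r}"
            )

    @property
    def stride_px(self) -> int:
        return int(round(self.tile_size_px * (1.0 - self.overlap_fraction)))


@dataclass(frozen=True)
class TileGrid:
    """Realised tile lattice for one image."""

    image_width_px: int
    image_height_px: int
    tile_size_px: int
    stride_px: int
    n_rows: int
    n_cols: int

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def to_dict(self) -> dict:
        return {
            "image_width_px": self.image_width_px,
            "image_height_px": self.image_height_px,
            "tile_size_px": self.tile_size_px,
            "stride_px": self.stride_px,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
        }


@dataclass(frozen=True)
class Tile:
    """A single fixed-size RGB crop plus its grid position and provenance."""

    pixels: np.ndarray  # (tile, tile, 3) uint8
    grid_row: int
    grid_col: int
    source_id: str = ""


def _axis_count(extent: int, tile: int, stride: int) -> int:
    if extent < tile:
        return 0
    return (extent - tile) // stride + 1


def make_grid(image_width_px: int, image_height_px: int, config: ChopConfig) -> TileGrid:
    """Grid geometry for an image without extracting any pixels."""
    stride = config.stride_px
    return TileGrid(
        image_width_px=image_width_px,
        image_height_px=image_height_px,
        tile_size_px=config.tile_size_px,
        stride_px=stride,
        n_rows=_axis_count(image_height_px, config.tile_size_px, stride),
        n_cols=_axis_count(image_width_px, config.tile_size_px, stride),
    )


def chop_image(
    image: np.ndarray, config: ChopConfig, source_id: str = ""
) -> tuple[TileGrid, list[Tile]]:
    """Chop an RGB image into overlapping square tiles, row-major.

    Parameters
    ----------
    image
        ``(H, W, 3)`` uint8 array (a grayscale ``(H, W)`` array is
        broadcast to three identical channels).
    config
        Tiling geometry.
    source_id
        Opaque identifier recorded on every emitted tile.

    Returns
    -------
    grid, tiles
        The grid geometry and exactly ``n_rows * n_cols`` tiles in
        row-major order.  An image smaller than the tile size in either
        dimension yields an empty grid (with a warning), not an error.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.repeat(image[:, :, None], 3, axis=2)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("image must contain at least one pixel")
    grid = make_grid(w, h, config)
    if grid.n_tiles == 0:
        warnings.warn(
            f"image {w}x{h} smaller than tile size {config.tile_size_px}; empty grid",
            stacklevel=2,
        )
        return grid, []
    t, s = config.tile_size_px, config.stride_px
    tiles = [
        Tile(
            pixels=np.ascontiguousarray(image[r * s : r * s + t, c * s : c * s + t]),
            grid_row=r,
            grid_col=c,
            source_id=source_id,
        )
        for r in range(grid.n_rows)
        for c in range(grid.n_cols)
    ]
    return grid, tiles


def iter_tile_positions(grid: TileGrid) -> Iterator[tuple[int, int]]:
    """Row-major ``(row, col)`` indices of the grid."""
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            yield r, c


def tile_bounds(grid: TileGrid, row: int, col: int) -> tuple[int, int, int, int]:
    """Half-open pixel rectangle ``(x0, y0, x1, y1)`` of tile ``(row, col)``."""
    if not (0 <= row < grid.n_rows) or not (0 <= col < grid.n_cols):
        raise IndexError(
            f"tile ({row}, {col}) outside grid of {grid.n_rows} rows x {grid.n_cols} cols"
        )
    x0 = col * grid.stride_px
    y0 = row * grid.stride_px
    return (x0, y0, x0 + grid.tile_size_px, y0 + grid.tile_size_px)
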