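"""Shared fixtures: small deterministic images and tile sets."""

from __future__ import annotations

import numpy as np
import pytest

from tilecover.dataset import LabeledTileSet


PURE_YELLOW = (255, 255, 0)
MID_GREEN = (0, 160, 0)


def uniform_image(h: int, w: int, color) -> np.ndarray:
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = color
    return img


def noisy_color_tiles(n: int, color, jitter: float, rng: np.random.Generator,
                      tile: int = 30) -> np.ndarray:
    base = np.array(color, dtype=np.float64)
    out = base + rng.normal(0.0, jitter, size=(n, tile, tile, 3))
    return np.clip(out, 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)


@pytest.fixture(scope="session")
def separable_tile_set() -> LabeledTileSet:
    """Yellow-vs-green tile set that a mean-channel threshold separates."""
    rng = np.random.default_rng(7)
    n = 120
    yellow = noisy_color_tiles(n, (230, 220, 40), 18.0, rng)
    green = noisy_color_tiles(n, (40, 140, 50), 18.0, rng)
    tiles = np.concatenate([yellow, green])
    labels = np.concatenate([np.ones(n, np.int8), np.zeros(n, np.int8)])
    split = np.array((["train"] * 96 + ["validation"] * 24) * 2, dtype="U10")
    return LabeledTileSet(tiles=tiles, labels=labels,
                          size_classes=[None] * (2 * n),
                          source_ids=["y"] * n + ["g"] * n, split=split)


def color_threshold_calls(tiles: np.ndarray) -> np.ndarray:
    """Independent oracle: yellow tiles have red mean far above blue mean."""
    tiles = tiles.astype(np.float64)
    return (tiles[..., 0].mean(axis=(1, 2)) - tiles[..., 2].mean(axis=(1, 2)) > 60).astype(np.int8)
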