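"""Hard-negative mining: the Model 1 -> Model 2 retraining step.

A first classifier ("Model 1") trained on clean positives and ordinary
negatives tends to fire on look-alike material — sun-lit leaves, other
yellow flowers.  Mining runs that model over images known to contain no
target, harvests every tile it calls positive (a guaranteed false
positive), adds those tiles to the negative *training* class, and retrains
from scratch.  The retrained classifier is "Model 2".  Harvested tiles
never enter the validation split, so the two models remain comparable on
the same held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import LabeledTileSet, SourceImage
from .errors import DatasetError
from .model import TileClassifier, TrainConfig, build_network
from .tiling import ChopConfig, chop_image

__all__ = ["MiningReport", "harvest_false_positives", "retrain_with_hard_negatives"]


@dataclass
class MiningReport:
    n_images_scanned: int
    n_tiles_scanned: int
    n_false_positive_tiles: int
    per_source: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_images_scanned": self.n_images_scanned,
            "n_tiles_scanned": self.n_tiles_scanned,
            "n_false_positive_tiles": self.n_false_positive_tiles,
            "per_source": dict(self.per_source),
        }


def harvest_false_positives(
    model: TileClassifier,
    negative_source_images: Sequence[SourceImage],
    chop: ChopConfig | None = None,
) -> tuple[MiningReport, np.ndarray, list[str]]:
    """Collect every tile the model calls positive on target-free images.

    The sources must be negative by construction, so a positive call is a
    false positive by definition.  Returns the mining report, the
    harvested tile pixels ``(k, t, t, 3)`` and their source ids.  Zero
    harvested tiles is a valid outcome.
    """
    chop = chop or ChopConfig()
    harvested: list[np.ndarray] = []
    ids: list[str] = []
    per_source: dict[str, int] = {}
    n_tiles = 0
    for src in negative_source_images:
        _, tiles = chop_image(src.image, chop, source_id=src.source_id)
        n_tiles += len(tiles)
        per_source.setdefault(src.source_id, 0)
        if not tiles:
            continue
        pixels = np.stack([t.pixels for t in tiles])
        calls = model.predict(pixels)
        for tile, call in zip(tiles, calls):
            if call:
                harvested.append(tile.pixels)
                ids.append(src.source_id)
                per_source[src.source_id] += 1
    report = MiningReport(
        n_images_scanned=len(negative_source_images),
        n_tiles_scanned=n_tiles,
        n_false_positive_tiles=len(harvested),
        per_source=per_source,
    )
    t = chop.tile_size_px
    pixels = (np.stack(harvested) if harvested
              else np.empty((0, t, t, 3), dtype=np.uint8))
    return report, pixels, ids


def add_hard_negatives(
    base_dataset: LabeledTileSet,
    harvested_pixels: np.ndarray,
    harvested_ids: Sequence[str] | None = None,
) -> LabeledTileSet:
    """Append harvested tiles to the negative training split of a dataset."""
    k = len(harvested_pixels)
    if k == 0:
        return base_dataset
    ids = list(harvested_ids) if harvested_ids is not None else ["mined"] * k
    extra = LabeledTileSet(
        tiles=np.asarray(harvested_pixels, dtype=np.uint8),
        labels=np.zeros(k, dtype=np.int8),
        size_classes=[None] * k,
        source_ids=ids,
        split=np.array(["train"] * k, dtype="U10"),
    )
    # leakage guard: a harvested tile must not duplicate a validation tile
    val = base_dataset.validation
    if len(val):
        val_keys = {v.tobytes() for v in val.tiles}
        for px in extra.tiles:
            if px.tobytes() in val_keys:
                raise DatasetError("harvested tile duplicates a validation tile (leakage)")
    return LabeledTileSet.concatenate([base_dataset, extra])


def retrain_with_hard_negatives(
    base_dataset: LabeledTileSet,
    harvested_pixels: np.ndarray,
    config: TrainConfig,
    harvested_ids: Sequence[str] | None = None,
) -> tuple[TileClassifier, LabeledTileSet]:
    """Rebuild the negative class and train Model 2 from scratch.

    The Model 2 training negatives are the union of the original negatives
    and the harvested tiles; the validation split is untouched.  With an
    empty harvest the dataset (and hence the training run) is identical to
    Model 1's.
    """
    augmented = add_hard_negatives(base_dataset, harvested_pixels, harvested_ids)
    tile_size = augmented.tiles.shape[1]
    model2 = build_network(tile_size, config)
    model2.fit(augmented.train, augmented.validation)
    return model2, augmented
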