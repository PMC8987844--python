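"""Labeled, size-stratified tile datasets: purity filtering and augmentation.

Positive training material comes from photographs dominated by the target
species in flower; negatives from photographs known to contain none of it.
Both are chopped into overlapping tiles.  Positive tiles are additionally
screened by the *green-purity rule*: a tile whose green-foliage pixel
fraction reaches the threshold (default 20 %) is discarded, mirroring the
manual curation of positive squares "mostly covered by yellow flowers".

Reference-object (primary inflorescence branch) pixel lengths stratify
positive sources into three size classes: S = 10-50 px, M = 51-100 px,
L = 101-300 px.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import AffineTransform, warp

from .errors import DatasetError
from .tiling import ChopConfig, Tile, chop_image

__all__ = [
    "SizeClass",
    "classify_size",
    "GreenRule",
    "purity_fraction",
    "SourceImage",
    "LabeledTileSet",
    "AugmentationConfig",
    "build_dataset",
    "augment_stream",
]

#: Inclusive reference-length bounds (pixels) per size class.
SIZE_BOUNDS: dict[str, tuple[int, int]] = {"S": (10, 50), "M": (51, 100), "L": (101, 300)}


class SizeClass(str, enum.Enum):
    S = "S"
    M = "M"
    L = "L"
    OUT_OF_RANGE = "OUT_OF_RANGE"


def classify_size(reference_length_px: int) -> SizeClass:
    """Map a reference-object pixel length to its size class.

    The reference object is the primary inflorescence branch; lengths of
    10-50 px are class S, 51-100 px M, 101-300 px L, anything else
    OUT_OF_RANGE.
    """
    if reference_length_px < 1:
        raise ValueError(f"reference length must be positive, got {reference_length_px}")
    for name, (lo, hi) in SIZE_BOUNDS.items():
        if lo <= reference_length_px <= hi:
            return SizeClass(name)
    return SizeClass.OUT_OF_RANGE


@dataclass(frozen=True)
class GreenRule:
    """HSV predicate identifying "green foliage" pixels.

    A pixel counts as green foliage when its hue lies in
    ``[hue_min_deg, hue_max_deg]`` and both saturation and value clear
    their floors.  The defaults bracket leaf greens while excluding the
    yellows of the target flowers; the 80-degree floor leaves headroom for
    flower pixels whose hue drifts upward under a cool colour balance.
    """

    hue_min_deg: float = 80.0
    hue_max_deg: float = 170.0
    saturation_min: float = 0.25
    value_min: float = 0.15

    def mask(self, rgb: np.ndarray) -> np.ndarray:
        """Boolean per-pixel foliage mask for an (H, W, 3) uint8 array."""
        hsv = rgb2hsv(np.asarray(rgb, dtype=np.uint8))
        hue_deg = hsv[..., 0] * 360.0
        return (
            (hue_deg >= self.hue_min_deg)
            & (hue_deg <= self.hue_max_deg)
            & (hsv[..., 1] >= self.saturation_min)
            & (hsv[..., 2] >= self.value_min)
        )


DEFAULT_GREEN_RULE = GreenRule()


def purity_fraction(tile: Tile | np.ndarray, rule: GreenRule = DEFAULT_GREEN_RULE) -> float:
    """Fraction of a tile's pixels matching the green-foliage predicate."""
    pixels = tile.pixels if isinstance(tile, Tile) else np.asarray(tile)
    return float(rule.mask(pixels).mean())


@dataclass(frozen=True)
class SourceImage:
    """One input photograph with provenance and (for positives) a size tag."""

    image: np.ndarray
    source_id: str
    size_class: SizeClass | None = None


@dataclass
class LabeledTileSet:
    """Fixed-size tiles with binary labels, size tags and split assignment.

    ``labels`` are 1 for the target species, 0 otherwise.  ``size_class``
    is only meaningful for positives (negatives carry ``None``).  The
    ``split`` tag is ``"train"`` or ``"validation"``; the two splits are
    disjoint by construction.
    """

    tiles: np.ndarray  # (n, t, t, 3) uint8
    labels: np.ndarray  # (n,) int8 in {0, 1}
    size_classes: list[SizeClass | None]
    source_ids: list[str]
    split: np.ndarray  # (n,) of "train" / "validation"

    def __post_init__(self) -> None:
        n = len(self.tiles)
        if not (len(self.labels) == len(self.size_classes) == len(self.source_ids) == len(self.split) == n):
            raise ValueError("per-tile columns must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.tiles)

    def subset(self, mask: np.ndarray) -> "LabeledTileSet":
        idx = np.flatnonzero(mask)
        return LabeledTileSet(
            tiles=self.tiles[idx],
            labels=self.labels[idx],
            size_classes=[self.size_classes[i] for i in idx],
            source_ids=[self.source_ids[i] for i in idx],
            split=self.split[idx],
        )

    @property
    def train(self) -> "LabeledTileSet":
        return self.subset(self.split == "train")

    @property
    def validation(self) -> "LabeledTileSet":
        return self.subset(self.split == "validation")

    def arrays(self, normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with X float32, rescaled to [0, 1] when ``normalize``."""
        x = self.tiles.astype(np.float32)
        if normalize:
            x = x / 255.0
        return x, self.labels.astype(np.float32)

    @staticmethod
    def concatenate(parts: Sequence["LabeledTileSet"]) -> "LabeledTileSet":
        return LabeledTileSet(
            tiles=np.concatenate([p.tiles for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            size_classes=[s for p in parts for s in p.size_classes],
            source_ids=[s for p in parts for s in p.source_ids],
            split=np.concatenate([p.split for p in parts]),
        )


@dataclass(frozen=True)
class AugmentationConfig:
    """Random tile augmentation: shifts, horizontal flip, zoom, rescale.

    Shift ranges are fractions of the tile edge; zoom draws a scale factor
    from ``[1 - zoom_range, 1 + zoom_range]``.  Every emitted tile is
    divided by ``rescale_divisor`` so intensities land in [0, 1].
    """

    width_shift_range: float = 0.1
    height_shift_range: float = 0.1
    horizontal_flip: bool = True
    zoom_range: float = 0.2
    rescale_divisor: float = 255.0

    def __post_init__(self) -> None:
        for name in ("width_shift_range", "height_shift_range", "zoom_range"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")

    @property
    def is_identity(self) -> bool:
        return (
            self.width_shift_range == 0
            and self.height_shift_range == 0
            and self.zoom_range == 0
            and not self.horizontal_flip
        )


def _random_transform(
    tile: np.ndarray, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply one random shift/flip/zoom to a float tile in [0, 1]."""
    t = tile.shape[0]
    out = tile
    if config.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.width_shift_range or config.height_shift_range or config.zoom_range:
        dx = rng.uniform(-config.width_shift_range, config.width_shift_range) * t
        dy = rng.uniform(-config.height_shift_range, config.height_shift_range) * t
        scale = 1.0 + rng.uniform(-config.zoom_range, config.zoom_range)
        centre = (t - 1) / 2.0
        # zoom about the tile centre, then translate
        tf = (
            AffineTransform(translation=(-centre, -centre))
            + AffineTransform(scale=(1.0 / scale, 1.0 / scale))
            + AffineTransform(translation=(centre + dx, centre + dy))
        )
        out = warp(out, tf.inverse, mode="reflect", order=1, preserve_range=True)
    return np.asarray(out, dtype=np.float32)


def augment_stream(
    tile_set: LabeledTileSet,
    config: AugmentationConfig | None = None,
    seed: int = 0,
) -> Iterator[tuple[np.ndarray, int]]:
    """Infinite seeded stream of (augmented normalized tile, label) pairs.

    Tiles are drawn uniformly at random from ``tile_set`` and transformed
    independently; labels are carried through unchanged.  Deterministic
    given the seed.
    """
    if len(tile_set) == 0:
        raise DatasetError("cannot augment an empty tile set")
    config = config or AugmentationConfig()
    rng = np.random.default_rng(seed)
    x = tile_set.tiles.astype(np.float32) / float(config.rescale_divisor)
    y = tile_set.labels
    n = len(tile_set)
    while True:
        i = int(rng.integers(n))
        if config.is_identity:
            yield x[i].copy(), int(y[i])
        else:
            yield np.clip(_random_transform(x[i], config, rng), 0.0, 1.0), int(y[i])


def _stratified_split(
    labels: np.ndarray, validation_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-label random train/validation assignment."""
    split = np.empty(len(labels), dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * validation_fraction))) if len(idx) > 1 else 0
        split[idx[:n_val]] = "validation"
        split[idx[n_val:]] = "train"
    return split.astype("U10")


def build_dataset(
    positive_sources: Sequence[SourceImage],
    negative_sources: Sequence[SourceImage],
    chop: ChopConfig | None = None,
    purity_threshold: float = 0.2,
    mix_sizes: bool = True,
    seed: int = 0,
    max_tiles_per_class: int | None = None,
    validation_fraction: float = 0.2,
    green_rule: GreenRule = DEFAULT_GREEN_RULE,
) -> LabeledTileSet:
    """Chop sources into labeled tiles, filter positives, split train/val.

    Positive tiles whose green-foliage fraction is at or above
    ``purity_threshold`` are excluded.  When ``mix_sizes`` is true and the
    positive sources carry several size classes, sampling under
    ``max_tiles_per_class`` is stratified so every size class present in
    the sources stays represented.  The train/validation split (default
    80/20) is stratified by label and seeded.
    """
    chop = chop or ChopConfig()
    rng = np.random.default_rng(seed)
    if not positive_sources or not negative_sources:
        raise DatasetError("need at least one positive and one negative source image")

    pos_tiles: list[np.ndarray] = []
    pos_sizes: list[SizeClass | None] = []
    pos_ids: list[str] = []
    for src in positive_sources:
        _, tiles = chop_image(src.image, chop, source_id=src.source_id)
        for tile in tiles:
            if purity_fraction(tile, green_rule) < purity_threshold:
                pos_tiles.append(tile.pixels)
                pos_sizes.append(src.size_class)
                pos_ids.append(src.source_id)
    if not pos_tiles:
        raise DatasetError(
            "positive class is empty after the green-purity filter "
            f"(threshold {purity_threshold})"
        )

    neg_tiles: list[np.ndarray] = []
    neg_ids: list[str] = []
    for src in negative_sources:
        _, tiles = chop_image(src.image, chop, source_id=src.source_id)
        for tile in tiles:
            neg_tiles.append(tile.pixels)
            neg_ids.append(src.source_id)
    if not neg_tiles:
        raise DatasetError("negative class is empty (sources yielded no tiles)")

    def _sample(n_avail: int, strata: list | None) -> np.ndarray:
        if max_tiles_per_class is None or n_avail <= max_tiles_per_class:
            return np.arange(n_avail)
        if strata is None or not mix_sizes:
            return rng.choice(n_avail, size=max_tiles_per_class, replace=False)
        # proportional draw within each size class, at least one per class
        strata_arr = np.array([s.value if s is not None else "?" for s in strata])
        keys = np.unique(strata_arr)
        quota = {k: max(1, int(round(max_tiles_per_class * (strata_arr == k).mean()))) for k in keys}
        chosen: list[np.ndarray] = []
        for k in keys:
            idx = np.flatnonzero(strata_arr == k)
            take = min(len(idx), quota[k])
            chosen.append(rng.choice(idx, size=take, replace=False))
        out = np.concatenate(chosen)
        return out[: max_tiles_per_class] if len(out) > max_tiles_per_class else out

    pi = _sample(len(pos_tiles), pos_sizes)
    ni = _sample(len(neg_tiles), None)

    tiles = np.stack([pos_tiles[i] for i in pi] + [neg_tiles[i] for i in ni])
    labels = np.concatenate([np.ones(len(pi), dtype=np.int8), np.zeros(len(ni), dtype=np.int8)])
    sizes: list[SizeClass | None] = [pos_sizes[i] for i in pi] + [None] * len(ni)
    ids = [pos_ids[i] for i in pi] + [neg_ids[i] for i in ni]
    split = _stratified_split(labels, validation_fraction, rng)
    return LabeledTileSet(tiles=tiles, labels=labels, size_classes=sizes, source_ids=ids, split=split)
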