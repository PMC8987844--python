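"""Seeded synthetic vegetation scenes with per-pixel ground truth.

The generator emulates the data regime of field photographs of a tall
yellow-flowering invader: dense dark-yellow inflorescence clusters on a
green/brown vegetated background, optionally with the two distractor
classes that drive real false positives — sun-lit leaves (bright,
low-saturation green-yellow) and non-target yellow flowers (paler, more
saturated yellow discs) — plus a sky band.  Every scene carries a binary
per-pixel truth mask of the target, so tile labels and cover fractions
can be derived exactly for any tiling.

Scenes are bit-reproducible from their seed.  Target clusters are
textured ellipses whose characteristic diameter is the scene's
inflorescence length; clusters are added and grown radially until the
mask reaches the requested cover fraction, which keeps the realised
cover within a few percent of the target.  A per-"camera" channel
gain/offset is applied last so that corpora from different simulated
cameras differ by a pure colour transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import GenerationError
from .dataset import SizeClass, SourceImage, classify_size
from .tiling import ChopConfig, make_grid

__all__ = ["CameraProfile", "SceneSpec", "Scene", "make_scene", "make_corpus"]

# Palette anchors (RGB). Target is "dark yellow"; the sunlit-leaf distractor
# is deliberately close to it in brightness to reproduce the real confusion.
TARGET_COLOR = np.array([200.0, 180.0, 30.0])
TARGET_JITTER = np.array([25.0, 25.0, 20.0])
FOLIAGE_COLOR = np.array([55.0, 105.0, 45.0])
SOIL_COLOR = np.array([125.0, 95.0, 60.0])
SKY_COLOR = np.array([170.0, 200.0, 235.0])
SUNLIT_LEAF_COLOR = np.array([215.0, 195.0, 55.0])
NONTARGET_FLOWER_COLOR = np.array([235.0, 225.0, 75.0])


@dataclass(frozen=True)
class CameraProfile:
    """Per-channel gain and offset emulating one camera's colour response."""

    name: str = "camera"
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def apply(self, image: np.ndarray) -> np.ndarray:
        return image * np.asarray(self.gain) + np.asarray(self.offset)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    width: int = 200
    height: int = 200
    target_cover_fraction: float = 0.3
    inflorescence_length_px: int = 40
    n_clusters: int | None = None  # None: as many as the cover needs
    soil_fraction: float = 0.12
    sky_fraction: float = 0.0
    sunlit_leaf_fraction: float = 0.0
    nontarget_yellow_flower_count: int = 0
    noise_sd: float = 4.0
    camera: CameraProfile = field(default_factory=CameraProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_cover_fraction <= 1.0:
            raise GenerationError("target_cover_fraction must be in [0, 1]")
        if self.target_cover_fraction > 0.95:
            raise GenerationError(
                "cover fractions above 0.95 are infeasible for elliptical clusters"
            )
        if self.inflorescence_length_px < 2:
            raise GenerationError("inflorescence_length_px must be >= 2")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")

    @property
    def size_class(self) -> SizeClass:
        return classify_size(self.inflorescence_length_px)


@dataclass
class Scene:
    """A rendered scene: RGB image, per-pixel truth mask, and its spec."""

    image: np.ndarray  # (H, W, 3) uint8
    truth_mask: np.ndarray  # (H, W) bool, True on target pixels
    spec: SceneSpec

    @property
    def cover_fraction(self) -> float:
        return float(self.truth_mask.mean())

    def tile_labels(self, chop: ChopConfig, positive_threshold: float = 0.5) -> np.ndarray:
        """Row-major binary tile labels: positive iff masked fraction >= threshold."""
        return (self.tile_mask_fractions(chop) >= positive_threshold).astype(np.int8)

    def tile_mask_fractions(self, chop: ChopConfig) -> np.ndarray:
        grid = make_grid(self.image.shape[1], self.image.shape[0], chop)
        t, s = grid.tile_size_px, grid.stride_px
        out = np.empty(grid.n_tiles)
        k = 0
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                out[k] = self.truth_mask[r * s : r * s + t, c * s : c * s + t].mean()
                k += 1
        return out

    def to_source(self, source_id: str | None = None) -> SourceImage:
        return SourceImage(
            image=self.image,
            source_id=source_id or f"{self.spec.camera.name}_seed{self.spec.seed}",
            size_class=self.spec.size_class,
        )


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    """Boolean mask of a rotated ellipse, evaluated on its bounding box only."""
    rmax = max(ry, rx)
    y0, y1 = max(0, int(cy - rmax - 1)), min(h, int(cy + rmax + 2))
    x0, x1 = max(0, int(cx - rmax - 1)), min(w, int(cx + rmax + 2))
    out = np.zeros((h, w), dtype=bool)
    if y0 >= y1 or x0 >= x1:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    out[y0:y1, x0:x1] = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return out


def _textured_fill(image: np.ndarray, mask: np.ndarray, color: np.ndarray,
                   jitter: np.ndarray, rng: np.random.Generator,
                   speckle: float = 0.0) -> None:
    n = int(mask.sum())
    if n == 0:
        return
    px = color + rng.normal(0.0, 1.0, size=(n, 3)) * jitter
    if speckle > 0:
        dark = rng.random(n) < speckle
        px[dark] *= 0.55
    image[mask] = px


def _low_freq_field(h: int, w: int, rng: np.random.Generator, cells: int = 10) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(max(2, h // cells), max(2, w // cells)))
    return resize(coarse, (h, w), order=1, mode="reflect", anti_aliasing=False)


def make_scene(spec: SceneSpec) -> Scene:
    """Render one scene deterministically from its spec."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    area = h * w

    # --- background: foliage with coarse brightness mottle
    mottle = _low_freq_field(h, w, rng)
    image = np.empty((h, w, 3))
    for ch in range(3):
        image[:, :, ch] = FOLIAGE_COLOR[ch] * (1.0 + 0.22 * mottle) + rng.normal(0, 9, (h, w))

    # --- soil patches
    soil_target = spec.soil_fraction * area
    soil_done = 0.0
    while soil_done < soil_target:
        r = rng.uniform(8, max(10, min(h, w) / 4))
        m = _ellipse_mask(h, w, rng.uniform(0, h), rng.uniform(0, w),
                          r * rng.uniform(0.5, 1.0), r, rng.uniform(0, np.pi))
        _textured_fill(image, m, SOIL_COLOR, np.array([14.0, 12.0, 10.0]), rng)
        soil_done += m.sum()

    # --- sky band at the top
    n_sky = int(round(spec.sky_fraction * h))
    if n_sky > 0:
        image[:n_sky] = SKY_COLOR + rng.normal(0, 5, (n_sky, w, 3))

    # --- sunlit-leaf distractors: elongated bright green-yellow blades
    sun_target = spec.sunlit_leaf_fraction * area
    sun_done = 0.0
    # patches span whole canopy regions, so some chopped tiles are fully sunlit
    while sun_done < sun_target:
        length = rng.uniform(25, 70)
        m = _ellipse_mask(h, w, rng.uniform(0, h), rng.uniform(0, w),
                          length * rng.uniform(0.35, 0.7), length, rng.uniform(0, np.pi))
        _textured_fill(image, m, SUNLIT_LEAF_COLOR, np.array([16.0, 14.0, 18.0]), rng)
        sun_done += m.sum()

    # --- non-target yellow flowers: small pale saturated discs
    for _ in range(spec.nontarget_yellow_flower_count):
        r = rng.uniform(3.0, 5.5)
        m = _ellipse_mask(h, w, rng.uniform(0, h), rng.uniform(0, w),
                          r * rng.uniform(0.8, 1.0), r, rng.uniform(0, np.pi))
        _textured_fill(image, m, NONTARGET_FLOWER_COLOR, np.array([6.0, 8.0, 14.0]), rng)

    # --- target clusters, grown until the mask hits the requested cover
    mask = np.zeros((h, w), dtype=bool)
    target_px = spec.target_cover_fraction * area
    if target_px > 0:
        rmax_len = spec.inflorescence_length_px / 2.0
        per_cluster_cap = None
        if spec.n_clusters:
            per_cluster_cap = target_px / spec.n_clusters
        clusters = 0
        while mask.sum() < target_px:
            clusters += 1
            if clusters > 10000:
                raise GenerationError(
                    f"could not reach cover {spec.target_cover_fraction} "
                    f"({mask.mean():.3f} realised)"
                )
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            aspect = rng.uniform(0.6, 1.0)
            theta = rng.uniform(0, np.pi)
            rmax = rmax_len
            if per_cluster_cap is not None:
                rmax = min(rmax, np.sqrt(per_cluster_cap / (np.pi * aspect)) + 1.0)
            r = 1.5
            while r <= rmax and mask.sum() < target_px:
                mask |= _ellipse_mask(h, w, cy, cx, r * aspect, r, theta)
                r += 1.0
        _textured_fill(image, mask, TARGET_COLOR, TARGET_JITTER, rng, speckle=0.12)

    # --- sensor noise, then the camera colour transform
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, image.shape)
    image = spec.camera.apply(image)
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    return Scene(image=image, truth_mask=mask, spec=spec)


def make_corpus(
    n_scenes: int,
    template: SceneSpec | None = None,
    cover_range: tuple[float, float] = (0.15, 0.6),
    length_range: tuple[int, int] = (10, 300),
    seed: int = 0,
) -> tuple[list[Scene], pd.DataFrame]:
    """Sample ``n_scenes`` scene specs around a template and render them.

    Cover fractions and inflorescence lengths are drawn uniformly from the
    given ranges (per-scene seeds derive from ``seed``), every other field
    comes from the template.  Returns the scenes plus a manifest recording
    each realised spec, its size class, and the achieved cover.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    template = template or SceneSpec()
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(n_scenes)]
    rng = np.random.default_rng(root)
    scenes: list[Scene] = []
    records = []
    for i in range(n_scenes):
        cover = float(rng.uniform(*cover_range)) if cover_range[1] > 0 else 0.0
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        spec = replace(template, target_cover_fraction=cover,
                       inflorescence_length_px=length, seed=child_seeds[i])
        scene = make_scene(spec)
        scenes.append(scene)
        records.append({
            "index": i, "seed": spec.seed, "camera": spec.camera.name,
            "width": spec.width, "height": spec.height,
            "target_cover_fraction": cover, "realized_cover": scene.cover_fraction,
            "inflorescence_length_px": length, "size_class": spec.size_class.value,
            "sunlit_leaf_fraction": spec.sunlit_leaf_fraction,
            "nontarget_yellow_flower_count": spec.nontarget_yellow_flower_count,
        })
    return scenes, pd.DataFrame.from_records(records)
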