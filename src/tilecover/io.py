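"""PNG/JPEG reading and writing for images, tiles and scene corpora."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .dataset import SizeClass, SourceImage

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

__all__ = ["load_image", "save_image", "list_images", "load_sources"]


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def save_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def list_images(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_SUFFIXES and p.is_file())


def load_sources(directory: str | Path,
                 size_class: SizeClass | None = None) -> list[SourceImage]:
    """Load every image in a directory as a SourceImage (id = file stem)."""
    return [SourceImage(image=load_image(p), source_id=p.stem, size_class=size_class)
            for p in list_images(directory)]
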