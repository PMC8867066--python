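"""Reading and writing images, label masks and tables.

Masks travel as one paletted PNG per fruit (0 = background, 1..8 = regions
in canonical order) plus a JSON label map; images as RGB PNG; tables as
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from citrusect.regions import REGION_NAMES, RegionMasks

__all__ = [
    "save_image",
    "load_image",
    "save_label_image",
    "load_label_image",
    "label_map",
    "save_label_map",
]

# 0=background then one distinct colour per region, in REGION_NAMES order
_PALETTE = [
    (0, 0, 0),
    (255, 255, 255),
    (230, 120, 30),
    (240, 228, 190),
    (120, 180, 255),
    (250, 170, 70),
    (120, 70, 30),
    (200, 200, 140),
    (255, 60, 60),
]


def label_map() -> dict[str, int]:
    return {r: i + 1 for i, r in enumerate(REGION_NAMES)}


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_label_image(path: str | Path, masks: RegionMasks) -> None:
    labels = masks.to_label_image()
    im = Image.fromarray(labels, mode="P")
    im.putpalette([c for rgb in _PALETTE for c in rgb])
    im.save(path)


def load_label_image(path: str | Path) -> RegionMasks:
    labels = np.asarray(Image.open(path))
    return RegionMasks.from_label_image(labels)


def save_label_map(path: str | Path) -> None:
    Path(path).write_text(json.dumps(label_map(), indent=2) + "\n")
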