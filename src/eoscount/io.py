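"""Persistence of images, masks, annotations and reports.

Masks are stored either as a 3-value label PNG (0=background, 1=intact,
2=not-intact) or as one {0,255} single-channel PNG per class.  Large
synthetic slides are written as tiled TIFF so they can be re-read
lazily; small extents may use PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .masks import CLASSES, LabelMaskStack

#: Extents at or below this side length may be written as PNG.
PNG_MAX_SIDE = 8192


def write_image(path: str | Path, image: np.ndarray, tile_size: int = 512) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, tile=(tile_size, tile_size), photometric="rgb")
    else:
        Image.fromarray(image).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path).convert("RGB"))


def write_label_mask(path: str | Path, masks: LabelMaskStack) -> None:
    """3-value label PNG (or TIFF for large extents)."""
    labels = masks.to_label_image()
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels, tile=(512, 512))
    else:
        Image.fromarray(labels, mode="L").save(path)


def read_label_mask(path: str | Path) -> LabelMaskStack:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = np.asarray(tifffile.imread(path))
    else:
        labels = np.asarray(Image.open(path).convert("L"))
    return LabelMaskStack.from_label_image(labels)


def write_class_masks(directory: str | Path, masks: LabelMaskStack, stem: str) -> list[Path]:
    """One {0,255} PNG per class: <stem>_<class>.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for cls in CLASSES:
        p = directory / f"{stem}_{cls}.png"
        Image.fromarray((masks.masks[cls] * np.uint8(255)), mode="L").save(p)
        paths.append(p)
    return paths


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def overlay_window(image: np.ndarray, offset: tuple[int, int], side: int,
                   color: tuple[int, int, int] = (255, 0, 0), thickness: int = 8) -> np.ndarray:
    """Draw the peak-window rectangle onto an RGB image copy."""
    out = np.array(image, dtype=np.uint8, copy=True)
    r, c = offset
    r1, c1 = min(r + side, out.shape[0]), min(c + side, out.shape[1])
    col = np.array(color, dtype=np.uint8)
    t = thickness
    out[r : min(r + t, r1), c:c1] = col
    out[max(r1 - t, r) : r1, c:c1] = col
    out[r:r1, c : min(c + t, c1)] = col
    out[r:r1, max(c1 - t, c) : c1] = col
    return out
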