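"""Lazy whole-slide pixel access.

Whole slides reach 1e8-1e10 pixels, far beyond what should ever be
decoded at once.  ``SlideSource`` exposes only ``extent`` and
``read_region``; the PEC scan reads one HPF window at a time, so peak
memory stays bounded by one window regardless of slide size.

Tiled TIFFs are read through tifffile's zarr adapter (only the tile
blocks intersecting the request are decoded).  PNGs and in-memory
arrays are for patches and tests, where full decode is fine.
"""

from __future__ import annotations

from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import tifffile
from PIL import Image

from .masks import Extent


@runtime_checkable
class SlideSource(Protocol):
    @property
    def extent(self) -> Extent: ...

    def read_region(self, row: int, col: int, height: int, width: int) -> np.ndarray:
        """RGB uint8 (height, width, 3) crop at the given offset."""
        ...


class ArraySlide:
    """In-memory slide (synthetic slides, tests)."""

    def __init__(self, image: np.ndarray):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB image, got {image.shape}")
        self._image = image
        self._extent = Extent.of(image)

    @property
    def extent(self) -> Extent:
        return self._extent

    def read_region(self, row: int, col: int, height: int, width: int) -> np.ndarray:
        self._check(row, col, height, width)
        return np.asarray(self._image[row : row + height, col : col + width], dtype=np.uint8)

    def _check(self, row: int, col: int, height: int, width: int) -> None:
        if row < 0 or col < 0 or row + height > self.extent.height or col + width > self.extent.width:
            raise ValueError(f"region ({row},{col})+({height},{width}) outside extent {self.extent.shape}")


class TiffSlide:
    """Tiled (optionally pyramidal) TIFF; level 0 is used."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._tif = tifffile.TiffFile(self.path)
        self._store = self._tif.aszarr(level=0)
        import zarr

        z = zarr.open(self._store, mode="r")
        self._array = z[0] if hasattr(z, "keys") and "0" in getattr(z, "keys", lambda: [])() else z
        self._extent = Extent(int(self._array.shape[0]), int(self._array.shape[1]))

    @property
    def extent(self) -> Extent:
        return self._extent

    def read_region(self, row: int, col: int, height: int, width: int) -> np.ndarray:
        if row < 0 or col < 0 or row + height > self.extent.height or col + width > self.extent.width:
            raise ValueError(f"region outside extent {self.extent.shape}")
        region = np.asarray(self._array[row : row + height, col : col + width])
        return region.astype(np.uint8)

    def close(self) -> None:
        self._tif.close()


def open_slide(source: str | Path | np.ndarray | SlideSource) -> SlideSource:
    """Open a slide from a path (TIFF/PNG), array, or pass through a source."""
    if isinstance(source, np.ndarray):
        return ArraySlide(source)
    if isinstance(source, (str, Path)):
        path = Path(source)
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            return TiffSlide(path)
        return ArraySlide(np.asarray(Image.open(path).convert("RGB")))
    if isinstance(source, SlideSource):
        return source
    raise TypeError(f"cannot open slide from {type(source)!r}")
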