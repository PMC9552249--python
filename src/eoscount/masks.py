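"""Core pixel-grid containers shared by every pipeline stage.

Coordinates are 0-based ``(row, col)``; regions are half-open
``[r, r + h) x [c, c + w)``.  The two eosinophil classes are ``intact``
(red cytoplasmic granules *and* a visible nucleus; the only class that
contributes to the diagnostic count) and ``not_intact`` (granule fields
or cells without a visible nucleus).  Pixels belonging to neither class
are implicitly non-eosinophil tissue/background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Eosinophil class names, in canonical order.
CLASSES: tuple[str, str] = ("intact", "not_intact")

#: Reference high-power-field area used for clinical counting (mm^2).
HPF_AREA_MM2: float = 0.3

#: Pixel pitch that maps a 0.3 mm^2 square HPF onto exactly 2144 px a side
#: (side sqrt(0.3) mm ~= 548 um), i.e. a 400X scan.
DEFAULT_MICRONS_PER_PIXEL: float = math.sqrt(HPF_AREA_MM2 * 1e6) / 2144.0


@dataclass(frozen=True)
class PixelScale:
    """Physical pixel pitch of a scan, in microns per pixel."""

    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be strictly positive")


@dataclass(frozen=True)
class Extent:
    """Height and width of a pixel grid."""

    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("extent dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @classmethod
    def of(cls, array: np.ndarray) -> "Extent":
        """Extent of a (H, W) or (H, W, C) array."""
        return cls(int(array.shape[0]), int(array.shape[1]))


@dataclass
class LabelMaskStack:
    """Per-class boolean masks over one pixel grid.

    ``masks[cls]`` is a boolean (H, W) array for each eosinophil class.
    Classes may overlap in principle, but every producer in this package
    (thresholding, rasterization) emits disjoint masks.
    """

    extent: Extent
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in CLASSES:
            if cls not in self.masks:
                self.masks[cls] = np.zeros(self.extent.shape, dtype=bool)
        for cls, m in self.masks.items():
            if cls not in CLASSES:
                raise ValueError(f"unknown class {cls!r}")
            if m.shape != self.extent.shape:
                raise ValueError(
                    f"mask for {cls!r} has shape {m.shape}, "
                    f"expected {self.extent.shape}"
                )
            self.masks[cls] = np.asarray(m, dtype=bool)

    def __getitem__(self, cls: str) -> np.ndarray:
        return self.masks[cls]

    @classmethod
    def empty(cls, extent: Extent) -> "LabelMaskStack":
        return cls(extent=extent)

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "LabelMaskStack":
        """Build from a 3-value label image (0=background, 1=intact, 2=not-intact)."""
        labels = np.asarray(labels)
        return cls(
            extent=Extent.of(labels),
            masks={"intact": labels == 1, "not_intact": labels == 2},
        )

    def to_label_image(self) -> np.ndarray:
        """Collapse to a 3-value label image; intact wins on (unexpected) overlap."""
        out = np.zeros(self.extent.shape, dtype=np.uint8)
        out[self.masks["not_intact"]] = 2
        out[self.masks["intact"]] = 1
        return out

    def crop(self, row: int, col: int, height: int, width: int) -> "LabelMaskStack":
        if row < 0 or col < 0 or row + height > self.extent.height or col + width > self.extent.width:
            raise ValueError("crop region outside extent")
        return LabelMaskStack(
            extent=Extent(height, width),
            masks={c: m[row : row + height, col : col + width] for c, m in self.masks.items()},
        )

    def equals(self, other: "LabelMaskStack") -> bool:
        return self.extent == other.extent and all(
            np.array_equal(self.masks[c], other.masks[c]) for c in CLASSES
        )
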