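"""Tile planning, mask fusion and high-power-field geometry.

The pipeline decomposes a slide twice: HPF-sized windows scanned at a
coarse stride, and network-input patches tiled inside each window.  Both
decompositions use the same planner.  Patch masks are recombined with a
pixelwise OR, so duplicated coverage from overlapping tiles is harmless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .masks import CLASSES, Extent, LabelMaskStack, PixelScale

TilePolicy = Literal["exact", "clamp"]


@dataclass(frozen=True)
class TileGrid:
    """Row-major top-left offsets of fixed-size square tiles over an extent."""

    extent: Extent
    tile: int
    stride: int
    offsets: tuple[tuple[int, int], ...]
    policy: TilePolicy

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self):
        return iter(self.offsets)

    @property
    def rows(self) -> tuple[int, ...]:
        return tuple(sorted({r for r, _ in self.offsets}))

    @property
    def cols(self) -> tuple[int, ...]:
        return tuple(sorted({c for _, c in self.offsets}))


def _axis_offsets(extent: int, tile: int, stride: int, policy: TilePolicy, axis: str) -> list[int]:
    if tile > extent:
        raise ValueError(f"tile exceeds extent on {axis} axis ({tile} > {extent})")
    if policy == "exact":
        residue = (extent - tile) % stride
        if residue:
            raise ValueError(
                f"exact tiling impossible on {axis} axis: "
                f"(extent - tile) = {extent - tile} leaves residue {residue} at stride {stride}"
            )
        return list(range(0, extent - tile + 1, stride))
    offsets = list(range(0, extent - tile + 1, stride))
    if offsets[-1] + tile < extent:
        offsets.append(extent - tile)  # flush-bottom/right tile
    return offsets


def plan_tiles(extent: Extent, tile: int, stride: int, policy: TilePolicy = "exact") -> TileGrid:
    """Plan square tiles of side ``tile`` at the given stride over ``extent``.

    Under ``exact`` the grid must divide evenly, as the standard
    geometries do (1200 px with 448/376 tiles -> 3x3; 2144 px with
    448/424 -> 5x5).  Under ``clamp`` an extra flush-right/bottom offset
    is appended per axis when the regular grid falls short, so the tiles
    always cover the full extent whenever ``stride <= tile``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = _axis_offsets(extent.height, tile, stride, policy, "row")
    cols = _axis_offsets(extent.width, tile, stride, policy, "col")
    offsets = tuple((r, c) for r in rows for c in cols)
    return TileGrid(extent=extent, tile=tile, stride=stride, offsets=offsets, policy=policy)


def fuse_masks(
    tiles: Iterable[tuple[tuple[int, int], LabelMaskStack]],
    extent: Extent,
) -> LabelMaskStack:
    """Recombine placed tile masks into one stack by pixelwise OR.

    Order-invariant and idempotent: a pixel is positive for a class iff
    any covering tile marks it positive.
    """
    out = LabelMaskStack.empty(extent)
    for (row, col), stack in tiles:
        h, w = stack.extent.shape
        if row < 0 or col < 0 or row + h > extent.height or col + w > extent.width:
            raise ValueError(f"tile at offset ({row}, {col}) extends beyond extent {extent.shape}")
        for cls in CLASSES:
            out.masks[cls][row : row + h, col : col + w] |= stack.masks[cls]
    return out


def hpf_side_pixels(hpf_area_mm2: float, scale: PixelScale = PixelScale()) -> int:
    """Side length, in pixels, of a square high-power field of the given area.

    At the default 400X scale the clinical 0.3 mm^2 HPF maps to a
    2144 px square (side ~548 um).
    """
    if not hpf_area_mm2 > 0:
        raise ValueError("HPF area must be positive")
    side_um = math.sqrt(hpf_area_mm2 * 1e6)
    return int(round(side_um / scale.microns_per_pixel))


def hpf_side_microns(hpf_area_mm2: float) -> int:
    """Side of a square HPF in whole microns (0.3 mm^2 -> 548 um)."""
    if not hpf_area_mm2 > 0:
        raise ValueError("HPF area must be positive")
    return int(round(math.sqrt(hpf_area_mm2 * 1e6)))


def coverage_mask(grid: TileGrid) -> np.ndarray:
    """Boolean map of pixels covered by at least one tile (used by tests/audit)."""
    covered = np.zeros(grid.extent.shape, dtype=bool)
    for r, c in grid.offsets:
        covered[r : r + grid.tile, c : c + grid.tile] = True
    return covered
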