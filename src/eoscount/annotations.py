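"""Point annotations, disk rasterization, patch filtering and dataset splits.

Experts mark only the *center* of each eosinophil; training masks are
produced by stamping a fixed-diameter disk (default 50 px, matching the
typical eosinophil footprint of ~2000 px^2) at every marked center.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .masks import CLASSES, Extent, LabelMaskStack

#: Default stamp diameter in pixels; a closed disk of this diameter
#: rasterizes to ~1963 px, inside the 1800-3000 px one-cell counting band.
DEFAULT_DISK_DIAMETER = 50

#: Patches whose background fraction falls on the wrong side of this
#: threshold are dropped before annotation (edge-frequency balancing).
DEFAULT_BACKGROUND_THRESHOLD = 0.15

#: Mean channel intensity (fraction of full scale) above which a pixel
#: counts as background glass.
DEFAULT_WHITE_THRESHOLD = 0.90


@dataclass(frozen=True)
class PointAnnotation:
    """A single expert-marked eosinophil center."""

    row: int
    col: int
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple
    val_ids: tuple
    train_fraction: float
    seed: int


def rasterize_annotations(
    points: Sequence[PointAnnotation],
    extent: Extent,
    diameter: int = DEFAULT_DISK_DIAMETER,
) -> LabelMaskStack:
    """Stamp a closed disk of the given diameter at each annotated center.

    Disk membership is squared distance from center <= (diameter/2)^2;
    disks are clipped at the image border and same-class disks merge by
    union (instances are recovered later by connected components).
    """
    if diameter < 1:
        raise ValueError("diameter must be >= 1")
    radius = diameter / 2.0
    r2 = radius * radius
    ir = int(np.ceil(radius))
    stack = LabelMaskStack.empty(extent)
    H, W = extent.shape
    for p in points:
        if not (0 <= p.row < H and 0 <= p.col < W):
            raise ValueError(f"annotation outside extent {extent.shape}: {p}")
        r0, r1 = max(0, p.row - ir), min(H, p.row + ir + 1)
        c0, c1 = max(0, p.col - ir), min(W, p.col + ir + 1)
        rr, cc = np.ogrid[r0:r1, c0:c1]
        disk = (rr - p.row) ** 2 + (cc - p.col) ** 2 <= r2
        stack.masks[p.cls][r0:r1, c0:c1] |= disk
    return stack


def background_fraction(patch: np.ndarray, white_threshold: float = DEFAULT_WHITE_THRESHOLD) -> float:
    """Fraction of pixels whose mean channel intensity is >= the white threshold.

    ``patch`` may be uint8 (full scale 255) or float in [0, 1].
    """
    patch = np.asarray(patch)
    if patch.size == 0:
        raise ValueError("patch is empty")
    if patch.dtype == np.uint8:
        mean = patch.reshape(patch.shape[0], patch.shape[1], -1).mean(axis=2) / 255.0
    else:
        mean = patch.reshape(patch.shape[0], patch.shape[1], -1).mean(axis=2)
    return float(np.mean(mean >= white_threshold))


FilterMode = Literal["drop_below", "drop_above"]


def filter_patches(
    patches: Sequence,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    mode: FilterMode = "drop_below",
    white_threshold: float = DEFAULT_WHITE_THRESHOLD,
    fraction_of=background_fraction,
) -> tuple[list, list[tuple[int, float]]]:
    """Drop patches by background fraction; returns (kept, removal log).

    ``drop_below`` (default, literal edge-balancing rule) removes
    patches with background fraction < ``threshold``; ``drop_above``
    (tissue-poor reading) removes patches with background fraction
    > 1 - ``threshold``.  The removal log holds (index, fraction) pairs,
    so kept + removed always reconstruct the input.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept: list = []
    removed: list[tuple[int, float]] = []
    for i, patch in enumerate(patches):
        frac = fraction_of(patch, white_threshold)
        drop = frac < threshold if mode == "drop_below" else frac > 1.0 - threshold
        if drop:
            removed.append((i, frac))
        else:
            kept.append(patch)
    return kept, removed


def split_dataset(ids: Sequence, train_fraction: float = 0.80, seed: int = 0) -> DatasetSplit:
    """Deterministic random train/validation split (default 80/20)."""
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    val = tuple(ids[i] for i in sorted(order[n_train:]))
    return DatasetSplit(train_ids=train, val_ids=val, train_fraction=train_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Annotation CSV I/O: columns image_id,row,col,class
# ---------------------------------------------------------------------------

def read_annotation_csv(path: str | Path) -> dict[str, list[PointAnnotation]]:
    df = pd.read_csv(path)
    required = {"image_id", "row", "col", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    out: dict[str, list[PointAnnotation]] = {}
    for image_id, row, col, cls in zip(df["image_id"], df["row"], df["col"], df["class"]):
        out.setdefault(str(image_id), []).append(
            PointAnnotation(row=int(row), col=int(col), cls=str(cls))
        )
    return out


def write_annotation_csv(path: str | Path, annotations: dict[str, Iterable[PointAnnotation]]) -> None:
    rows = [
        {"image_id": image_id, "row": p.row, "col": p.col, "class": p.cls}
        for image_id, pts in annotations.items()
        for p in pts
    ]
    pd.DataFrame(rows, columns=["image_id", "row", "col", "class"]).to_csv(path, index=False)
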