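"""Synthetic H&E-like slides with known eosinophil ground truth.

The generator renders a pink tissue-textured background with white
glass regions and plants disk-shaped eosinophils: *intact* cells as
red-granular disks with a dark nucleus blob, *not-intact* cells as
paler granule fields without a nucleus.  It emits, from the same
geometry, the label masks, center-point annotations, per-window intact
counts and the true peak eosinophil count on exactly the window grid
the pipeline scans — so every downstream stage can be verified against
construction.

Appearance is deliberately schematic: it supports oracle-driven
pipeline tests and toy model training, not histological realism.
Default cell radii are drawn so that disk areas concentrate near the
~2050 px footprint of a typical segmented eosinophil, inside the
(1800, 3000] px one-cell counting band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .annotations import PointAnnotation
from .geometry import plan_tiles
from .masks import CLASSES, Extent, LabelMaskStack
from .quantify import (
    CountingRule,
    DEFAULT_HPF_SIDE,
    DEFAULT_SCAN_STRIDE,
    HPFResult,
    count_eosinophils,
)

#: Default radius range (pixels): areas ~1840-2250 px, mean ~2045 px.
DEFAULT_RADIUS_RANGE = (24.2, 26.8)

# H&E-ish palette (uint8 RGB)
TISSUE_BASE = np.array([231, 191, 201], dtype=np.float32)
GLASS = np.array([247, 247, 247], dtype=np.float32)
INTACT_GRANULE = np.array([214, 60, 70], dtype=np.float32)
NOT_INTACT_GRANULE = np.array([222, 128, 96], dtype=np.float32)
NUCLEUS = np.array([88, 58, 132], dtype=np.float32)


@dataclass(frozen=True)
class ClusterSpec:
    """Plant ``count`` cells of one class inside an HPF-sized window."""

    center: tuple[int, int]
    cls: str
    count: int
    allow_merge: bool = False


@dataclass
class SyntheticSlideSpec:
    extent: Extent = field(default_factory=lambda: Extent(4288, 4288))
    n_intact: int = 10
    n_not_intact: int = 6
    radius_range: tuple[float, float] = DEFAULT_RADIUS_RANGE
    clusters: tuple[ClusterSpec, ...] = ()
    glass_fraction: float = 0.08
    noise_scale: int = 16
    min_separation: float = 8.0  # gap between disk rims, px
    hpf_side: int = DEFAULT_HPF_SIDE
    scan_stride: int = DEFAULT_SCAN_STRIDE
    seed: int = 0


@dataclass
class PlantedObject:
    row: int
    col: int
    radius: float
    cls: str


@dataclass
class SyntheticGroundTruth:
    masks: LabelMaskStack
    points: list[PointAnnotation]
    objects: list[PlantedObject]
    window_counts: list[HPFResult]
    pec: int
    peak_window: HPFResult


class OvercrowdingError(RuntimeError):
    """Requested object count infeasible at the minimum separation."""


def _place_objects(spec: SyntheticSlideSpec, rng: np.random.Generator) -> list[PlantedObject]:
    H, W = spec.extent.shape
    rmax = spec.radius_range[1]
    margin = int(np.ceil(rmax)) + 1
    placed: list[PlantedObject] = []

    def try_place(cls: str, lo: tuple[int, int], hi: tuple[int, int], check_sep: bool) -> None:
        for _ in range(2000):
            r = int(rng.integers(max(margin, lo[0]), min(H - margin, hi[0])))
            c = int(rng.integers(max(margin, lo[1]), min(W - margin, hi[1])))
            radius = float(rng.uniform(*spec.radius_range))
            if check_sep:
                ok = all(
                    (r - o.row) ** 2 + (c - o.col) ** 2
                    >= (radius + o.radius + spec.min_separation) ** 2
                    for o in placed
                )
                if not ok:
                    continue
            placed.append(PlantedObject(row=r, col=c, radius=radius, cls=cls))
            return
        raise OvercrowdingError(
            f"could not place a {cls} object at min separation {spec.min_separation}"
        )

    half = min(spec.hpf_side, H, W) // 2
    for cluster in spec.clusters:
        if cluster.cls not in CLASSES:
            raise ValueError(f"unknown cluster class {cluster.cls!r}")
        if cluster.count == 0:
            continue
        cr, cc = cluster.center
        lo = (max(margin, cr - half + margin), max(margin, cc - half + margin))
        hi = (min(H - margin, cr + half - margin), min(W - margin, cc + half - margin))
        if cluster.allow_merge:
            for _ in range(cluster.count):
                try_place(cluster.cls, lo, hi, check_sep=False)
            continue
        # dense clusters go on a jittered grid: feasible packing without merging
        boxh, boxw = hi[0] - lo[0], hi[1] - lo[1]
        d = 2 * rmax + 3  # rim gap >= 3 px keeps 8-connected components apart
        ncols = int(np.ceil(np.sqrt(cluster.count)))
        nrows = int(np.ceil(cluster.count / ncols))
        if (ncols - 1) * d > boxw or (nrows - 1) * d > boxh:
            raise OvercrowdingError(
                f"cluster of {cluster.count} {cluster.cls} cells does not fit one HPF window"
            )
        step_r = d if nrows == 1 else min(boxh / (nrows - 1), d + 12)
        step_c = d if ncols == 1 else min(boxw / (ncols - 1), d + 12)
        jit_r, jit_c = (step_r - d) / 2, (step_c - d) / 2  # keeps rim gap >= 3 px
        slots = [(i, j) for i in range(nrows) for j in range(ncols)]
        rng.shuffle(slots)
        for (i, j) in slots[: cluster.count]:
            r = lo[0] + i * step_r + (boxh - (nrows - 1) * step_r) / 2 + rng.uniform(-jit_r, jit_r)
            c = lo[1] + j * step_c + (boxw - (ncols - 1) * step_c) / 2 + rng.uniform(-jit_c, jit_c)
            radius = float(rng.uniform(*spec.radius_range))
            placed.append(PlantedObject(row=int(round(r)), col=int(round(c)),
                                        radius=radius, cls=cluster.cls))
    for _ in range(spec.n_intact):
        try_place("intact", (0, 0), (H, W), check_sep=True)
    for _ in range(spec.n_not_intact):
        try_place("not_intact", (0, 0), (H, W), check_sep=True)
    return placed


def _background(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    H, W = spec.extent.shape
    s = spec.noise_scale
    gh, gw = -(-H // s), -(-W // s)
    coarse = rng.normal(0.0, 1.0, size=(gh, gw)).astype(np.float32)
    texture = np.kron(coarse, np.ones((s, s), dtype=np.float32))[:H, :W]
    img = TISSUE_BASE[None, None, :] + texture[:, :, None] * np.array([6, 10, 8], np.float32)
    img += rng.normal(0.0, 3.0, size=(H, W, 1)).astype(np.float32)
    # white glass blobs
    n_blobs = max(1, int(spec.glass_fraction * H * W / (140 * 140 * np.pi)))
    for _ in range(n_blobs):
        br, bc = rng.uniform(0, H), rng.uniform(0, W)
        ar, ac = rng.uniform(80, 200), rng.uniform(80, 200)
        r0, r1 = max(0, int(br - ar)), min(H, int(br + ar) + 1)
        c0, c1 = max(0, int(bc - ac)), min(W, int(bc + ac) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = ((np.arange(r0, r1, dtype=np.float32) - br) / ar) ** 2
        xx = ((np.arange(c0, c1, dtype=np.float32) - bc) / ac) ** 2
        inside = yy[:, None] + xx[None, :] <= 1.0
        img[r0:r1, c0:c1][inside] = GLASS + rng.normal(0, 1.5, size=3).astype(np.float32)
    return img


def _stamp_cell(img: np.ndarray, masks: LabelMaskStack, obj: PlantedObject,
                rng: np.random.Generator) -> None:
    H, W = img.shape[:2]
    ir = int(np.ceil(obj.radius))
    r0, r1 = max(0, obj.row - ir), min(H, obj.row + ir + 1)
    c0, c1 = max(0, obj.col - ir), min(W, obj.col + ir + 1)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - obj.row) ** 2 + (cc - obj.col) ** 2
    disk = d2 <= obj.radius**2
    base = INTACT_GRANULE if obj.cls == "intact" else NOT_INTACT_GRANULE
    granules = rng.normal(0.0, 14.0, size=(r1 - r0, c1 - c0, 1)).astype(np.float32)
    patch = img[r0:r1, c0:c1]
    patch[disk] = (base[None, :] + granules[disk]).astype(np.float32)
    if obj.cls == "intact":
        # eccentric nucleus blob
        nr = obj.row + int(rng.integers(-4, 5))
        nc = obj.col + int(rng.integers(-4, 5))
        nrad = obj.radius * 0.45
        nucleus = ((rr - nr) ** 2 + (cc - nc) ** 2 <= nrad**2) & disk
        patch[nucleus] = NUCLEUS[None, :] + rng.normal(0, 6.0, size=(int(nucleus.sum()), 3)).astype(np.float32)
    masks.masks[obj.cls][r0:r1, c0:c1] |= disk


def window_grid_counts(
    masks: LabelMaskStack,
    hpf_side: int,
    scan_stride: int,
    rule: CountingRule = CountingRule(),
) -> list[HPFResult]:
    """Intact counts over the clamped HPF window grid of the truth masks."""
    extent = masks.extent
    side = min(hpf_side, extent.height, extent.width)
    grid = plan_tiles(extent, side, scan_stride, policy="clamp")
    out = []
    for (r, c) in grid:
        crop = masks.crop(r, c, side, side)
        count, _ = count_eosinophils(crop, "intact", rule)
        out.append(HPFResult(offset=(r, c), side=side, count=count))
    return out


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a synthetic slide and its exhaustive ground truth."""
    rng = np.random.default_rng(spec.seed)
    objects = _place_objects(spec, rng)
    img = _background(spec, rng)
    masks = LabelMaskStack.empty(spec.extent)
    for obj in objects:
        _stamp_cell(img, masks, obj, rng)
    image = np.clip(img, 0, 255).astype(np.uint8)
    window_counts = window_grid_counts(masks, spec.hpf_side, spec.scan_stride)
    peak = max(window_counts, key=lambda wr: wr.count)
    # first maximal window in row-major order, matching the pipeline tie-break
    peak = next(wr for wr in window_counts if wr.count == peak.count)
    truth = SyntheticGroundTruth(
        masks=masks,
        points=[PointAnnotation(row=o.row, col=o.col, cls=o.cls) for o in objects],
        objects=objects,
        window_counts=window_counts,
        pec=peak.count,
        peak_window=peak,
    )
    return image, truth


def generate_patch_dataset(
    tile: int = 448,
    n: int = 8,
    class_fractions: dict[str, float] | None = None,
    radius_range: tuple[float, float] = DEFAULT_RADIUS_RANGE,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, LabelMaskStack]], dict[str, list[PointAnnotation]]]:
    """Cut ``n`` training tiles from synthetic slides.

    ``class_fractions`` asks that at least the given fraction of tiles
    contain >= 1 object of each class (default 0.5 intact, 0.3
    not-intact).  Returns the (tile image, truth mask) pairs plus the
    tile-local point annotations keyed by tile id, ready for CSV export.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = {"intact": 0.5, "not_intact": 0.3}
    if class_fractions:
        fractions.update(class_fractions)
    if any(not 0 <= f <= 1 for f in fractions.values()):
        raise ValueError(f"infeasible class-balance request: {fractions}")

    need = {cls: int(np.ceil(fractions[cls] * n)) for cls in CLASSES}
    if sum(need.values()) > n:
        raise ValueError(f"infeasible class-balance request for n={n}: {fractions}")
    quota = []  # per-tile guaranteed class, or None
    for cls in CLASSES:
        quota += [cls] * need[cls]
    quota += [None] * (n - len(quota))

    rng = np.random.default_rng(seed)
    slide_side = max(4 * tile, 1024)
    tiles: list[tuple[np.ndarray, LabelMaskStack]] = []
    annotations: dict[str, list[PointAnnotation]] = {}
    # cap planted objects so placement stays feasible at min separation
    max_objects = int(slide_side**2 * 0.25 / (5 * 3500))
    per_slide = max(1, min(n // 2, max_objects))
    idx = 0
    while idx < n:
        spec = SyntheticSlideSpec(
            extent=Extent(slide_side, slide_side),
            n_intact=3 * per_slide,
            n_not_intact=2 * per_slide,
            hpf_side=min(DEFAULT_HPF_SIDE, slide_side),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = generate_slide(spec)
        by_class = {cls: [o for o in truth.objects if o.cls == cls] for cls in CLASSES}
        for _ in range(per_slide):
            if idx >= n:
                break
            want = quota[idx]
            if want is not None and by_class[want]:
                obj = by_class[want][int(rng.integers(len(by_class[want])))]
                m = min(40, tile // 4)
                r0 = int(np.clip(obj.row - int(rng.integers(m, tile - m)), 0, slide_side - tile))
                c0 = int(np.clip(obj.col - int(rng.integers(m, tile - m)), 0, slide_side - tile))
            else:
                r0 = int(rng.integers(0, slide_side - tile + 1))
                c0 = int(rng.integers(0, slide_side - tile + 1))
            crop_img = image[r0 : r0 + tile, c0 : c0 + tile].copy()
            crop_mask = LabelMaskStack(
                extent=Extent(tile, tile),
                masks={c: truth.masks.masks[c][r0 : r0 + tile, c0 : c0 + tile].copy() for c in CLASSES},
            )
            tile_id = f"tile_{idx:04d}"
            annotations[tile_id] = [
                PointAnnotation(row=p.row - r0, col=p.col - c0, cls=p.cls)
                for p in truth.points
                if r0 <= p.row < r0 + tile and c0 <= p.col < c0 + tile
            ]
            tiles.append((crop_img, crop_mask))
            idx += 1
    return tiles, annotations
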