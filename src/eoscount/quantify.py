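"""Eosinophil counting, peak-eosinophil-count scanning and disease-activity calls.

Counting is area-based: after segmentation the typical intact
eosinophil occupies ~2050 px, so a connected region counts as one cell
when its area lies in (1800, 3000] px, and each additional 2000 px
beyond 3000 adds one cell (merged clusters).  The slide-level statistic
is the peak eosinophil count (PEC): the maximum intact count over all
HPF-sized windows scanned across the slide, compared against the
clinical activity cutoff of 15 intact eosinophils per 0.3 mm^2 HPF.
Only intact eosinophils contribute to the PEC; not-intact counts are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy import stats as scipy_stats

from .geometry import fuse_masks, plan_tiles
from .masks import CLASSES, Extent, HPF_AREA_MM2, LabelMaskStack, PixelScale
from .segmentation import SegmenterContract, threshold_probabilities
from .slide import SlideSource, open_slide

DEFAULT_HPF_SIDE = 2144
DEFAULT_SCAN_STRIDE = 500
DEFAULT_PATCH = 448
DEFAULT_PATCH_STRIDE = 424
DEFAULT_ACTIVITY_THRESHOLD = 15

IncrementMode = Literal["floor", "ceil"]


@dataclass(frozen=True)
class CountingRule:
    """Area-to-count rule for connected eosinophil regions (pixels)."""

    min_area: int = 1800        # exclusive lower bound of the one-cell band
    one_cell_max: int = 3000    # inclusive upper bound of the one-cell band
    increment: int = 2000       # extra area per additional cell beyond the band
    increment_mode: IncrementMode = "floor"

    def __post_init__(self) -> None:
        if not 0 < self.min_area < self.one_cell_max:
            raise ValueError("need 0 < min_area < one_cell_max")
        if self.increment <= 0:
            raise ValueError("increment must be positive")


@dataclass(frozen=True)
class ConnectedComponent:
    cls: str
    area: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    label: int = 0


@dataclass(frozen=True)
class HPFResult:
    offset: tuple[int, int]
    side: int
    count: int


@dataclass
class SlideReport:
    slide_id: str
    pec: int
    window: HPFResult
    active: bool
    threshold: int
    counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "pec": self.pec,
            "window": {"row": self.window.offset[0], "col": self.window.offset[1], "side": self.window.side},
            "active": self.active,
            "threshold": self.threshold,
            "counts": dict(self.counts),
        }


_STRUCTURES = {8: np.ones((3, 3), dtype=bool), 4: ndimage.generate_binary_structure(2, 1)}


def count_from_area(area: int, rule: CountingRule = CountingRule()) -> int:
    """Eosinophils in one connected region of the given pixel area."""
    if area < 0:
        raise ValueError("area must be >= 0")
    if area <= rule.min_area:
        return 0
    if area <= rule.one_cell_max:
        return 1
    extra = (area - rule.one_cell_max) / rule.increment
    extra = int(np.floor(extra)) if rule.increment_mode == "floor" else int(np.ceil(extra))
    return 1 + extra


def connected_components(
    mask: np.ndarray, cls: str, connectivity: int = 8
) -> tuple[np.ndarray, list[ConnectedComponent]]:
    """Label a boolean mask and describe its components."""
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    comps = []
    if n:
        slices = ndimage.find_objects(labels)
        rs, cs = np.nonzero(labels)
        lab = labels[rs, cs]
        areas = np.bincount(lab, minlength=n + 1)
        rsum = np.bincount(lab, weights=rs, minlength=n + 1)
        csum = np.bincount(lab, weights=cs, minlength=n + 1)
        for k in range(n):
            sl = slices[k]
            comps.append(
                ConnectedComponent(
                    cls=cls,
                    area=int(areas[k + 1]),
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    centroid=(rsum[k + 1] / areas[k + 1], csum[k + 1] / areas[k + 1]),
                    label=k + 1,
                )
            )
    return labels, comps


def count_eosinophils(
    masks: LabelMaskStack,
    cls: str = "intact",
    rule: CountingRule = CountingRule(),
    connectivity: int = 8,
) -> tuple[int, list[ConnectedComponent]]:
    """Area-rule count of one class over 8-connected components."""
    _, comps = connected_components(masks.masks[cls], cls, connectivity)
    total = sum(count_from_area(c.area, rule) for c in comps)
    return total, comps


def eos_density(
    count: int,
    window_area_px: float,
    scale: PixelScale = PixelScale(),
    reference_area_mm2: float = HPF_AREA_MM2,
) -> float:
    """Normalize a count to eosinophils per reference HPF area (0.3 mm^2)."""
    if window_area_px <= 0:
        raise ValueError("window area must be positive")
    window_mm2 = window_area_px * (scale.microns_per_pixel**2) / 1e6
    return count * reference_area_mm2 / window_mm2


def peak_eos_count(
    slide,
    segmenter: SegmenterContract,
    hpf_side: int = DEFAULT_HPF_SIDE,
    scan_stride: int = DEFAULT_SCAN_STRIDE,
    patch: int = DEFAULT_PATCH,
    patch_stride: int = DEFAULT_PATCH_STRIDE,
    rule: CountingRule = CountingRule(),
    prob_threshold: float = 0.5,
    connectivity: int = 8,
    emit_mask: bool = False,
) -> tuple[HPFResult, LabelMaskStack | None, list[HPFResult]]:
    """Sliding-HPF scan for the peak intact-eosinophil count.

    HPF windows are enumerated at ``scan_stride`` with a flush edge
    window (clamp policy); slides smaller than one HPF collapse to a
    single clamped window.  Each window is read lazily from the slide
    source, tiled into network patches, segmented, OR-fused and counted,
    so memory stays bounded by one window plus one patch.  Ties keep the
    first maximal window in row-major scan order.

    Returns (peak window, fused whole-slide mask if ``emit_mask``,
    all per-window results).
    """
    src: SlideSource = open_slide(slide)
    extent = src.extent
    win_h = min(hpf_side, extent.height)
    win_w = min(hpf_side, extent.width)
    if win_h != win_w:
        win_h = win_w = min(win_h, win_w)  # keep windows square on tiny slides
    windows = plan_tiles(extent, win_h, scan_stride, policy="clamp")

    full_mask = LabelMaskStack.empty(extent) if emit_mask else None
    results: list[HPFResult] = []
    best: HPFResult | None = None
    for (wr, wc) in windows:
        region = src.read_region(wr, wc, win_h, win_w)
        window_extent = Extent(win_h, win_w)
        try:
            patches = plan_tiles(window_extent, min(patch, win_h), patch_stride, policy="exact")
        except ValueError:
            patches = plan_tiles(window_extent, min(patch, win_h), patch_stride, policy="clamp")
        placed = []
        for (pr, pc) in patches:
            tile = region[pr : pr + patches.tile, pc : pc + patches.tile]
            probs = segmenter(tile, origin=(wr + pr, wc + pc))
            if probs.shape[1:] != tile.shape[:2]:
                raise ValueError(
                    f"segmenter returned extent {probs.shape[1:]} for tile {tile.shape[:2]}"
                )
            placed.append(((pr, pc), threshold_probabilities(probs, prob_threshold)))
        fused = fuse_masks(placed, window_extent)
        count, _ = count_eosinophils(fused, "intact", rule, connectivity)
        res = HPFResult(offset=(wr, wc), side=win_h, count=count)
        results.append(res)
        if best is None or count > best.count:
            best = res
        if full_mask is not None:
            for cls in CLASSES:
                full_mask.masks[cls][wr : wr + win_h, wc : wc + win_w] |= fused.masks[cls]
    assert best is not None
    return best, full_mask, results


def classify_activity(pec: int, threshold: int = DEFAULT_ACTIVITY_THRESHOLD) -> bool:
    """Active disease iff the peak count reaches the cutoff (>= 15/HPF)."""
    if pec < 0:
        raise ValueError("PEC must be >= 0")
    return pec >= threshold


def ranked_slide_list(reports: Sequence[SlideReport]) -> list[SlideReport]:
    """Slides ordered by descending PEC; ties by slide id ascending."""
    return sorted(reports, key=lambda r: (-r.pec, r.slide_id))


def roc_sweep(
    pecs: Sequence[float], true_labels: Sequence[bool]
) -> tuple[list[tuple[float, float, float]], float, float]:
    """Threshold sweep of the PEC classifier.

    Thresholds are the midpoints between consecutive distinct PEC values
    plus sentinels below and above the range; a slide is called active
    when PEC >= threshold.  Returns ([(threshold, FPR, TPR), ...],
    trapezoidal AUC, and the accuracy-maximizing threshold — smallest on
    ties).
    """
    pecs = np.asarray(pecs, dtype=float)
    labels = np.asarray(true_labels, dtype=bool)
    if pecs.size == 0 or pecs.shape != labels.shape:
        raise ValueError("pecs and labels must be non-empty and equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC sweep needs both classes present")
    distinct = np.unique(pecs)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    points = []
    best_acc, best_thr = -1.0, None
    for thr in thresholds:
        pred = pecs >= thr
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        tpr, fpr = tp / n_pos, fp / n_neg
        acc = (tp + (n_neg - fp)) / labels.size
        points.append((float(thr), fpr, tpr))
        if acc > best_acc:
            best_acc, best_thr = acc, float(thr)
    pts = sorted((fpr, tpr) for _, fpr, tpr in points)
    xs = [0.0] + [p[0] for p in pts] + [1.0]
    ys = [0.0] + [p[1] for p in pts] + [1.0]
    auc = float(np.trapezoid(ys, xs))
    return points, auc, best_thr


def count_calibration(
    pred_counts: Sequence[float], true_counts: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS fit of predicted on true counts: (slope, intercept, R^2, MAE)."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.size < 3 or pred.shape != true.shape:
        raise ValueError("need >= 3 paired counts")
    if np.ptp(true) == 0:
        raise ValueError("true counts are constant; fit is degenerate")
    fit = scipy_stats.linregress(true, pred)
    mae = float(np.abs(pred - true).mean())
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), mae


def segment_error_stats(
    pred: LabelMaskStack,
    truth: LabelMaskStack,
    rule: CountingRule = CountingRule(),
    connectivity: int = 8,
    min_component_area: int = 0,
) -> dict[str, float]:
    """Component-level false discovery rate and relative counting error.

    A predicted component is a true positive when it overlaps at least
    one same-class truth component by >= 1 pixel; each truth component
    can absorb only one prediction, matched greedily by overlap size.
    The counting error rate is |predicted count - true count| /
    max(true count, 1) using the area counting rule, pooled over the
    two classes.

    ``min_component_area`` restricts the FDR to components above that
    area (e.g. the counting rule's one-cell lower bound), so that
    sub-counting noise specks do not dominate the discovery statistics;
    the counting error always uses all components (the rule itself
    zeroes the small ones).
    """
    n_pred_total = 0
    n_fp_total = 0
    pred_count = 0
    true_count = 0
    for cls in CLASSES:
        pred_labels, all_pred_comps = connected_components(pred.masks[cls], cls, connectivity)
        true_labels, all_true_comps = connected_components(truth.masks[cls], cls, connectivity)
        pred_comps = [c for c in all_pred_comps if c.area > min_component_area]
        true_comps = [c for c in all_true_comps if c.area > min_component_area]
        pred_count += sum(count_from_area(c.area, rule) for c in all_pred_comps)
        true_count += sum(count_from_area(c.area, rule) for c in all_true_comps)
        n_pred_total += len(pred_comps)
        if not pred_comps:
            continue
        allowed_true = {c.label for c in true_comps}
        overlaps = []
        for pc in pred_comps:
            region = pred_labels == pc.label
            hit = true_labels[region]
            for t in np.unique(hit[hit > 0]):
                if int(t) in allowed_true:
                    overlaps.append((int(np.count_nonzero(hit == t)), pc.label, int(t)))
        overlaps.sort(key=lambda x: (-x[0], x[1], x[2]))
        matched_pred: set[int] = set()
        matched_true: set[int] = set()
        for size, p_lab, t_lab in overlaps:
            if p_lab in matched_pred or t_lab in matched_true:
                continue
            matched_pred.add(p_lab)
            matched_true.add(t_lab)
        n_fp_total += len(pred_comps) - len(matched_pred)
    fdr = n_fp_total / n_pred_total if n_pred_total else 0.0
    err_rate = abs(pred_count - true_count) / max(true_count, 1)
    return {
        "segment_fdr": float(fdr),
        "counting_error_rate": float(err_rate),
        "pred_components": n_pred_total,
        "pred_count": pred_count,
        "true_count": true_count,
    }
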