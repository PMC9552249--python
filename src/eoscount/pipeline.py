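"""End-to-end orchestration: slides in, reports and ranked list out.

The three outputs per run mirror clinical use: a segmented slide mask
(optional), the per-slide peak eosinophil count with its window, and a
ranked slide list for triage.  When pathologist activity labels are
supplied, cohort classification metrics are computed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .config import PipelineConfig
from .masks import LabelMaskStack
from .metrics import classification_metrics
from .quantify import (
    CountingRule,
    SlideReport,
    classify_activity,
    peak_eos_count,
    ranked_slide_list,
)
from .segmentation import SegmenterContract
from .slide import open_slide


@dataclass
class PipelineResult:
    reports: list[SlideReport]
    ranked: list[SlideReport]
    masks: dict[str, LabelMaskStack] = field(default_factory=dict)
    cohort_metrics: dict[str, float] | None = None

    def to_dict(self) -> dict:
        ranked_ids = [r.slide_id for r in self.ranked]
        payload = {
            "reports": [
                {**r.to_dict(), "ranked_position": ranked_ids.index(r.slide_id) + 1}
                for r in self.reports
            ],
            "ranked": ranked_ids,
        }
        if self.cohort_metrics is not None:
            payload["cohort_metrics"] = self.cohort_metrics
        return payload


def rule_from_config(config: PipelineConfig) -> CountingRule:
    return CountingRule(
        min_area=config.min_area,
        one_cell_max=config.one_cell_max,
        increment=config.increment,
        increment_mode=config.increment_mode,
    )


def run_pipeline(
    slides: Sequence[tuple[str, object]],
    config: PipelineConfig,
    segmenters: SegmenterContract | dict[str, SegmenterContract],
    true_labels: dict[str, bool] | None = None,
    emit_masks: bool = False,
) -> PipelineResult:
    """Run the PEC pipeline over (slide_id, slide source) pairs.

    ``segmenters`` is one shared segmenter or a per-slide mapping (the
    ground-truth oracle is necessarily per-slide).  Deterministic given
    the config and segmenter seeds.
    """
    if len(slides) == 0:
        raise ValueError("no slides given")
    rule = rule_from_config(config)
    reports: list[SlideReport] = []
    masks: dict[str, LabelMaskStack] = {}
    for slide_id, source in slides:
        segmenter = segmenters[slide_id] if isinstance(segmenters, dict) else segmenters
        peak, full_mask, window_results = peak_eos_count(
            open_slide(source),
            segmenter,
            hpf_side=config.hpf_side,
            scan_stride=config.scan_stride,
            patch=config.patch,
            patch_stride=config.patch_stride,
            rule=rule,
            prob_threshold=config.prob_threshold,
            connectivity=config.connectivity,
            emit_mask=emit_masks,
        )
        counts = {"intact": peak.count, "not_intact": 0}
        if full_mask is not None:
            from .quantify import count_eosinophils

            masks[slide_id] = full_mask
            counts["not_intact"] = count_eosinophils(full_mask, "not_intact", rule,
                                                     config.connectivity)[0]
        reports.append(
            SlideReport(
                slide_id=slide_id,
                pec=peak.count,
                window=peak,
                active=classify_activity(peak.count, config.activity_threshold),
                threshold=config.activity_threshold,
                counts=counts,
            )
        )
    ranked = ranked_slide_list(reports)
    cohort = None
    if true_labels is not None:
        pred = [r.active for r in reports]
        true = [bool(true_labels[r.slide_id]) for r in reports]
        cohort = classification_metrics(pred, true)
    return PipelineResult(reports=reports, ranked=ranked, masks=masks, cohort_metrics=cohort)
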