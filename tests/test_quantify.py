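"""Counting rule, densities, PEC scanning, ROC and calibration statistics."""

import numpy as np
import pytest

from eoscount.annotations import PointAnnotation, rasterize_annotations
from eoscount.masks import CLASSES, Extent, LabelMaskStack, PixelScale
from eoscount.quantify import (
    CountingRule,
    HPFResult,
    SlideReport,
    classify_activity,
    count_calibration,
    count_eosinophils,
    count_from_area,
    eos_density,
    peak_eos_count,
    ranked_slide_list,
    roc_sweep,
    segment_error_stats,
)
from eoscount.segmentation import oracle_segmenter
from eoscount.synthesize import SyntheticSlideSpec, generate_slide

from conftest import random_mask_stack


def brute_force_count(area, rule):
    """Enumerate the area rule cell by cell."""
    if area <= rule.min_area:
        return 0
    count, covered = 1, rule.one_cell_max
    while covered < area:
        covered += rule.increment
        count += 1
    if rule.increment_mode == "floor" and covered > area:
        count -= 1
    return max(count, 1)


class TestCountFromArea:
    def test_typical_eosinophil_area_counts_one(self):
        assert count_from_area(2050) == 1

    def test_band_boundaries(self):
        assert count_from_area(1800) == 0
        assert count_from_area(1801) == 1
        assert count_from_area(3000) == 1
        assert count_from_area(3001, CountingRule(increment_mode="ceil")) == 2

    def test_merged_regions_floor_mode(self):
        assert count_from_area(5000) == 2
        assert count_from_area(7001) == 3

    @pytest.mark.parametrize("mode", ["floor", "ceil"])
    def test_sampled_areas_match_enumeration_oracle(self, mode):
        rule = CountingRule(increment_mode=mode)
        for area in range(0, 20001, 97):
            assert count_from_area(area, rule) == brute_force_count(area, rule), area

    def test_non_decreasing_in_area(self):
        counts = [count_from_area(a) for a in range(0, 12000, 50)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            count_from_area(-1)


class TestCountEosinophils:
    def test_empty_mask_zero(self):
        assert count_eosinophils(LabelMaskStack.empty(Extent(100, 100)))[0] == 0

    def test_three_disjoint_disks_count_three(self):
        pts = [PointAnnotation(60, 60, "intact"), PointAnnotation(60, 200, "intact"),
               PointAnnotation(200, 130, "intact")]
        stack = rasterize_annotations(pts, Extent(300, 300))
        count, comps = count_eosinophils(stack, "intact")
        assert count == 3 and len(comps) == 3
        for c in comps:
            assert 1800 < c.area <= 3000

    def test_merged_component_uses_area_rule(self):
        stack = LabelMaskStack.empty(Extent(100, 100))
        stack.masks["intact"][10:49, 10:90] = True  # 39 x 80 = 3120 px
        count, comps = count_eosinophils(stack, "intact")
        assert len(comps) == 1 and comps[0].area == 3120
        assert count == 1  # floor mode: 120 extra px below the 2000 increment

    def test_translation_invariance(self, rng):
        base = LabelMaskStack.empty(Extent(200, 200))
        rr, cc = np.mgrid[0:200, 0:200]
        base.masks["intact"][(rr - 50) ** 2 + (cc - 50) ** 2 <= 625] = True
        shifted = LabelMaskStack.empty(Extent(200, 200))
        shifted.masks["intact"][(rr - 120) ** 2 + (cc - 140) ** 2 <= 625] = True
        assert count_eosinophils(base)[0] == count_eosinophils(shifted)[0]

    def test_8_vs_4_connectivity(self):
        stack = LabelMaskStack.empty(Extent(10, 10))
        stack.masks["intact"][2, 2] = stack.masks["intact"][3, 3] = True
        assert len(count_eosinophils(stack, connectivity=8)[1]) == 1
        assert len(count_eosinophils(stack, connectivity=4)[1]) == 2


class TestDensity:
    def test_reference_window_identity(self):
        side = 2144
        assert eos_density(15, side * side) == pytest.approx(15.0, rel=1e-3)

    def test_zero_count(self):
        assert eos_density(0, 12345.0) == 0.0

    def test_linear_scaling_half_area(self):
        scale = PixelScale(1.0)  # 1 um/px
        px_03mm2 = 0.3e6
        assert eos_density(5, px_03mm2 / 2, scale) == pytest.approx(10.0)

    def test_non_positive_area(self):
        with pytest.raises(ValueError):
            eos_density(1, 0.0)


class TestClassifyActivity:
    @pytest.mark.parametrize("pec,active", [(15, True), (14, False), (0, False), (40, True)])
    def test_threshold_partition(self, pec, active):
        assert classify_activity(pec) is active

    def test_negative_pec(self):
        with pytest.raises(ValueError):
            classify_activity(-1)


class TestRankedList:
    @staticmethod
    def report(slide_id, pec):
        return SlideReport(slide_id=slide_id, pec=pec,
                           window=HPFResult((0, 0), 100, pec), active=pec >= 15, threshold=15)

    def test_descending_pec(self):
        reports = [self.report("a", 3), self.report("b", 40), self.report("c", 15)]
        assert [r.pec for r in ranked_slide_list(reports)] == [40, 15, 3]

    def test_ties_by_id(self):
        reports = [self.report("z", 5), self.report("a", 5), self.report("m", 5)]
        assert [r.slide_id for r in ranked_slide_list(reports)] == ["a", "m", "z"]

    def test_random_lists_match_sort_oracle(self, rng):
        for _ in range(10):
            reports = [self.report(f"s{i}", int(rng.integers(0, 30))) for i in range(12)]
            ranked = ranked_slide_list(reports)
            oracle = sorted(reports, key=lambda r: (-r.pec, r.slide_id))
            assert [r.slide_id for r in ranked] == [r.slide_id for r in oracle]


class TestRocSweep:
    def test_perfect_separation_auc_one(self):
        pecs = [1, 2, 3, 20, 25, 30]
        labels = [False, False, False, True, True, True]
        _, auc, thr = roc_sweep(pecs, labels)
        assert auc == pytest.approx(1.0)
        assert 3 < thr <= 20

    def test_best_threshold_matches_exhaustive_oracle(self):
        pecs = [2.0, 9.0, 13.0, 16.0, 21.0, 5.0]
        labels = [False, False, True, True, True, False]
        _, _, thr = roc_sweep(pecs, labels)
        candidates = sorted(set(pecs))
        best_acc, best_thr = -1, None
        mids = [candidates[0] - 1] + [
            (a + b) / 2 for a, b in zip(candidates, candidates[1:])
        ] + [candidates[-1] + 1]
        for t in mids:
            acc = np.mean([(p >= t) == l for p, l in zip(pecs, labels)])
            if acc > best_acc:
                best_acc, best_thr = acc, t
        assert thr == best_thr

    def test_labels_independent_of_pecs_auc_near_half(self, rng):
        n = 3000
        pecs = rng.integers(0, 40, size=n)
        labels = rng.random(n) < 0.5
        _, auc, _ = roc_sweep(pecs, labels)
        assert abs(auc - 0.5) < 3 / np.sqrt(n)  # permutation-scale bound

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_sweep([1, 2, 3], [True, True, True])


class TestCountCalibration:
    def test_identity_fit(self):
        true = [0, 2, 5, 9, 14]
        slope, intercept, r2, mae = count_calibration(true, true)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)
        assert mae == 0.0

    def test_constant_offset(self):
        true = np.array([0, 2, 5, 9, 14], dtype=float)
        slope, intercept, _, mae = count_calibration(true + 1, true)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(1.0)
        assert mae == pytest.approx(1.0)

    def test_noisy_pairs_match_closed_form_ols(self, rng):
        true = rng.integers(0, 50, size=40).astype(float)
        pred = true + rng.normal(0, 2, size=40)
        slope, intercept, r2, _ = count_calibration(pred, true)
        x, y = true, pred
        beta = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        alpha = y.mean() - beta * x.mean()
        assert slope == pytest.approx(beta)
        assert intercept == pytest.approx(alpha)
        resid = y - (alpha + beta * x)
        assert r2 == pytest.approx(1 - resid.var() / y.var())

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            count_calibration([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


def brute_force_segment_stats(pred, truth, rule):
    """Exhaustive greedy bipartite matching oracle on component pixel sets."""
    from eoscount.quantify import connected_components, count_from_area

    n_pred = n_fp = 0
    pc_total = tc_total = 0
    for cls in CLASSES:
        plab, pcomps = connected_components(pred.masks[cls], cls)
        tlab, tcomps = connected_components(truth.masks[cls], cls)
        pc_total += sum(count_from_area(c.area, rule) for c in pcomps)
        tc_total += sum(count_from_area(c.area, rule) for c in tcomps)
        n_pred += len(pcomps)
        pairs = []
        for p in pcomps:
            pset = set(zip(*np.nonzero(plab == p.label)))
            for t in tcomps:
                tset = set(zip(*np.nonzero(tlab == t.label)))
                ov = len(pset & tset)
                if ov:
                    pairs.append((ov, p.label, t.label))
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_p, used_t = set(), set()
        for ov, pl, tl in pairs:
            if pl in used_p or tl in used_t:
                continue
            used_p.add(pl)
            used_t.add(tl)
        n_fp += len(pcomps) - len(used_p)
    return (n_fp / n_pred if n_pred else 0.0,
            abs(pc_total - tc_total) / max(tc_total, 1))


class TestSegmentErrorStats:
    def test_perfect_prediction(self, rng):
        truth = rasterize_annotations(
            [PointAnnotation(60, 60, "intact"), PointAnnotation(200, 200, "not_intact")],
            Extent(300, 300),
        )
        stats = segment_error_stats(truth, truth)
        assert stats["segment_fdr"] == 0.0
        assert stats["counting_error_rate"] == 0.0

    def test_one_spurious_among_four(self):
        extent = Extent(400, 400)
        truth = rasterize_annotations(
            [PointAnnotation(60, 60, "intact"), PointAnnotation(60, 200, "intact"),
             PointAnnotation(200, 60, "intact")], extent)
        pred = rasterize_annotations(
            [PointAnnotation(60, 60, "intact"), PointAnnotation(60, 200, "intact"),
             PointAnnotation(200, 60, "intact"), PointAnnotation(330, 330, "intact")], extent)
        stats = segment_error_stats(pred, truth)
        assert stats["segment_fdr"] == pytest.approx(0.25)

    def test_no_predictions_fdr_zero(self):
        truth = rasterize_annotations([PointAnnotation(50, 50, "intact")], Extent(100, 100))
        stats = segment_error_stats(LabelMaskStack.empty(truth.extent), truth)
        assert stats["segment_fdr"] == 0.0
        assert stats["counting_error_rate"] == 1.0

    def test_min_component_area_excludes_specks_from_fdr(self, rng):
        extent = Extent(300, 300)
        truth = rasterize_annotations([PointAnnotation(150, 150, "intact")], extent)
        pred = rasterize_annotations([PointAnnotation(150, 150, "intact")], extent)
        pred.masks["intact"][5, 5] = True  # 1-px noise speck
        assert segment_error_stats(pred, truth)["segment_fdr"] == pytest.approx(0.5)
        filtered = segment_error_stats(pred, truth, min_component_area=1800)
        assert filtered["segment_fdr"] == 0.0

    def test_randomized_masks_match_matching_oracle(self, rng):
        rule = CountingRule(min_area=2, one_cell_max=6, increment=4)
        for _ in range(15):
            pred = random_mask_stack(rng, 14, 14, p=0.35)
            truth = random_mask_stack(rng, 14, 14, p=0.35)
            stats = segment_error_stats(pred, truth, rule)
            fdr, err = brute_force_segment_stats(pred, truth, rule)
            assert stats["segment_fdr"] == pytest.approx(fdr)
            assert stats["counting_error_rate"] == pytest.approx(err)


class TestPeakEosCount:
    # small geometry: 300-px HPF windows, 100-px patches, exact 3x3 patch grid
    KW = dict(hpf_side=300, scan_stride=150, patch=100, patch_stride=100)

    @staticmethod
    def blank_slide(side=600):
        return np.full((side, side, 3), 230, np.uint8)

    def test_blank_slide_pec_zero(self):
        truth = LabelMaskStack.empty(Extent(600, 600))
        peak, _, _ = peak_eos_count(self.blank_slide(), oracle_segmenter(truth), **self.KW)
        assert peak.count == 0

    def test_planted_cluster_recovered(self):
        extent = Extent(600, 600)
        pts = [PointAnnotation(100 + 55 * i, 120, "intact") for i in range(4)]
        truth = rasterize_annotations(pts, extent)
        peak, _, _ = peak_eos_count(self.blank_slide(), oracle_segmenter(truth), **self.KW)
        assert peak.count == 4

    def test_max_of_two_clusters(self):
        extent = Extent(600, 600)
        pts = [PointAnnotation(60, 60 + 55 * i, "intact") for i in range(3)]
        pts += [PointAnnotation(430, 350 + 52 * i, "intact") for i in range(4)]
        truth = rasterize_annotations(pts, extent)
        peak, _, _ = peak_eos_count(self.blank_slide(), oracle_segmenter(truth), **self.KW)
        assert peak.count == 4

    def test_matches_brute_force_whole_slide_scan(self):
        spec = SyntheticSlideSpec(
            extent=Extent(900, 900), n_intact=9, n_not_intact=4,
            hpf_side=300, scan_stride=150, seed=5,
        )
        image, truth = generate_slide(spec)
        peak, _, windows = peak_eos_count(image, oracle_segmenter(truth.masks), **self.KW)
        # brute force: decode everything at once, count every window crop
        from eoscount.geometry import plan_tiles

        best = -1
        best_off = None
        for (r, c) in plan_tiles(truth.masks.extent, 300, 150, "clamp"):
            crop = truth.masks.crop(r, c, 300, 300)
            count, _ = count_eosinophils(crop, "intact")
            if count > best:
                best, best_off = count, (r, c)
        assert peak.count == best
        assert peak.offset == best_off

    def test_tie_break_first_row_major_window(self):
        extent = Extent(600, 600)
        truth = rasterize_annotations([PointAnnotation(450, 450, "intact")], extent)
        peak, _, windows = peak_eos_count(self.blank_slide(), oracle_segmenter(truth), **self.KW)
        maxima = [w.offset for w in windows if w.count == peak.count]
        assert peak.offset == maxima[0]

    def test_adding_cell_in_peak_window_monotone(self):
        extent = Extent(600, 600)
        pts = [PointAnnotation(100, 100, "intact"), PointAnnotation(100, 200, "intact")]
        truth1 = rasterize_annotations(pts, extent)
        peak1, _, _ = peak_eos_count(self.blank_slide(), oracle_segmenter(truth1), **self.KW)
        pts.append(PointAnnotation(200, 150, "intact"))
        truth2 = rasterize_annotations(pts, extent)
        peak2, _, _ = peak_eos_count(self.blank_slide(), oracle_segmenter(truth2), **self.KW)
        assert peak2.count >= peak1.count

    def test_slide_smaller_than_hpf_single_clamped_window(self):
        extent = Extent(200, 200)
        truth = rasterize_annotations([PointAnnotation(100, 100, "intact")], extent)
        peak, _, windows = peak_eos_count(
            np.full((200, 200, 3), 230, np.uint8), oracle_segmenter(truth),
            hpf_side=300, scan_stride=150, patch=100, patch_stride=100,
        )
        assert len(windows) == 1
        assert windows[0].side == 200
        assert peak.count == 1

    def test_emitted_mask_matches_truth_with_perfect_oracle(self):
        extent = Extent(600, 600)
        truth = rasterize_annotations(
            [PointAnnotation(100, 100, "intact"), PointAnnotation(400, 500, "not_intact")],
            extent,
        )
        _, full_mask, _ = peak_eos_count(
            self.blank_slide(), oracle_segmenter(truth), emit_mask=True, **self.KW
        )
        assert full_mask.equals(truth)
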