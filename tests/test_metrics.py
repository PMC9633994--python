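"""Lesion extraction, the 10%/70% detection rule, DSC, F1 and cohort averaging."""

from collections import deque

import numpy as np
import pytest

from nlseg import (
    LabelMask,
    cohort_evaluate,
    dsc,
    evaluate_case,
    extract_lesions,
    false_positive_volume,
    lesion_f1,
    match_lesions,
)
from nlseg.metrics import LesionComponent

from conftest import cube_mask, random_mask


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Independent flood-fill component oracle."""
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and {6: abs(dx) + abs(dy) + abs(dz) == 1,
             18: abs(dx) + abs(dy) + abs(dz) <= 2,
             26: True}[connectivity]
    ]
    seen = set()
    comps = []
    fg = set(map(tuple, np.argwhere(mask > 0).tolist()))
    for start in sorted(fg):
        if start in seen:
            continue
        comp = set()
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.add(v)
            for o in offsets:
                nb = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if nb in fg and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def component(voxels, volume=None, voxel_volume=1.0) -> LesionComponent:
    voxels = frozenset(voxels)
    return LesionComponent(voxels, volume if volume is not None else len(voxels) * voxel_volume)


def box(corner, size):
    return [
        (corner[0] + i, corner[1] + j, corner[2] + k)
        for i in range(size[0]) for j in range(size[1]) for k in range(size[2])
    ]


class TestExtractLesions:
    def test_agrees_with_bfs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = random_mask(rng, p=0.06)
            ours = extract_lesions(mask, min_volume_mm3=0.0)
            oracle = bfs_components(mask.data)
            assert sorted(map(sorted, (c.voxel_indices for c in ours))) == sorted(
                map(sorted, oracle)
            )

    @pytest.mark.parametrize("connectivity", [6, 18])
    def test_reduced_connectivity_matches_oracle(self, connectivity):
        rng = np.random.default_rng(1)
        for _ in range(20):
            mask = random_mask(rng, p=0.1)
            ours = extract_lesions(mask, min_volume_mm3=0.0, connectivity=connectivity)
            assert len(ours) == len(bfs_components(mask.data, connectivity))

    def test_two_separated_cubes(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[1:3, 1:3, 1:3] = 1
        data[6:8, 6:8, 6:8] = 1
        comps = extract_lesions(LabelMask(data, (1, 1, 1)))
        assert len(comps) == 2
        assert sorted(c.volume_mm3 for c in comps) == [8.0, 8.0]

    def test_single_voxel_dropped_by_3mm3_rule(self):
        mask = cube_mask((8, 8, 8), (3, 3, 3), 1)
        assert extract_lesions(mask) == []

    def test_volume_uses_voxel_spacing(self):
        mask = cube_mask((8, 8, 8), (2, 2, 2), 2, spacing=(1.0, 1.0, 0.5))
        comps = extract_lesions(mask)
        assert len(comps) == 1
        assert comps[0].volume_mm3 == pytest.approx(8 * 0.5)

    def test_empty_mask(self):
        assert extract_lesions(LabelMask(np.zeros((5, 5, 5), np.uint8), (1, 1, 1))) == []


class TestMatchLesions:
    def test_perfect_match(self):
        g = component(box((2, 2, 2), (3, 3, 3)))
        table = match_lesions([g], [g])
        assert (table.n_tp, table.n_fp, table.n_fn) == (1, 0, 0)

    def test_five_percent_overlap_fails(self):
        gt = component(box((0, 0, 0), (10, 10, 1)))  # 100 voxels
        pred = component(box((0, 0, 0), (5, 1, 1)))  # 5 voxels inside
        table = match_lesions([gt], [pred])
        assert (table.n_tp, table.n_fn, table.n_fp) == (0, 1, 1)

    def test_eighty_percent_outside_fails(self):
        gt = component(box((5, 0, 0), (10, 1, 1)))  # 10 voxels
        pred = component(box((0, 0, 0), (50, 1, 1)))  # covers gt + 40 outside
        table = match_lesions([gt], [pred])
        assert (table.n_tp, table.n_fn, table.n_fp) == (0, 1, 1)

    def test_outside_denominator_gt_reading(self):
        # 10-voxel gt fully covered, 6 voxels outside: outside/pred = 6/16 <= 0.7
        # but outside/gt = 0.6 <= 0.7 as well -> detected under both readings;
        # with 8 outside voxels, outside/gt = 0.8 fails only the gt reading
        gt = component(box((2, 0, 0), (10, 1, 1)))
        pred = component(box((0, 0, 0), (18, 1, 1)))
        assert match_lesions([gt], [pred], outside_denominator="pred").n_tp == 1
        assert match_lesions([gt], [pred], outside_denominator="gt").n_tp == 0

    def test_union_of_fragments_detects(self):
        gt = component(box((0, 0, 0), (4, 4, 1)))  # 16 voxels
        frag1 = component(box((0, 0, 0), (2, 4, 1)))
        frag2 = component(box((2, 0, 0), (2, 4, 1)))
        table = match_lesions([gt], [frag1, frag2])
        assert table.n_tp == 1 and table.matched_pred == 2 and table.n_fp == 0

    def test_tp_plus_fn_equals_gt_count(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            gt_mask = random_mask(rng, p=0.05)
            pred_mask = random_mask(rng, p=0.05)
            gt = extract_lesions(gt_mask, 0.0)
            pred = extract_lesions(pred_mask, 0.0)
            table = match_lesions(gt, pred)
            assert table.n_tp + table.n_fn == len(gt)

    def test_detection_monotone_in_inside_coverage(self):
        gt = component(box((0, 0, 0), (4, 4, 2)))  # 32 voxels
        outside = box((10, 10, 10), (2, 1, 1))
        small = component(box((0, 0, 0), (2, 2, 2)) + outside)  # 8 inside
        larger = component(box((0, 0, 0), (4, 4, 2)) + outside)  # all 32 inside
        if match_lesions([gt], [small]).n_tp == 1:
            assert match_lesions([gt], [larger]).n_tp == 1


class TestDsc:
    def test_identical_masks(self):
        m = cube_mask((8, 8, 8), (2, 2, 2), 3)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = cube_mask((10, 10, 10), (0, 0, 0), 2)
        b = cube_mask((10, 10, 10), (6, 6, 6), 2)
        assert dsc(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), np.uint8)
        g = np.zeros((10, 10, 10), np.uint8)
        a[0:1, 0:10, 0:10] = 1  # 100 voxels
        g[0:1, 0:5, 0:10] = 1
        g[1:2, 0:5, 0:10] = 1  # 100 voxels, overlap 50
        assert dsc(LabelMask(a, (1, 1, 1)), LabelMask(g, (1, 1, 1))) == 0.5

    def test_both_empty_convention(self):
        e = LabelMask(np.zeros((4, 4, 4), np.uint8), (1, 1, 1))
        assert dsc(e, e) == 1.0

    def test_one_empty(self):
        e = LabelMask(np.zeros((8, 8, 8), np.uint8), (1, 1, 1))
        m = cube_mask((8, 8, 8), (2, 2, 2), 2)
        assert dsc(e, m) == 0.0 and dsc(m, e) == 0.0

    def test_symmetric_and_mirror_invariant(self):
        rng = np.random.default_rng(3)
        a = random_mask(rng, p=0.2)
        b = random_mask(rng, p=0.2)
        assert dsc(a, b) == dsc(b, a)
        am = LabelMask(np.flip(a.data, 0).copy(), a.spacing)
        bm = LabelMask(np.flip(b.data, 0).copy(), b.spacing)
        assert dsc(am, bm) == dsc(a, b)

    def test_grid_mismatch_rejected(self):
        a = cube_mask((8, 8, 8), (0, 0, 0), 2)
        b = cube_mask((9, 9, 9), (0, 0, 0), 2)
        with pytest.raises(ValueError, match="mismatch"):
            dsc(a, b)


class TestLesionF1:
    def test_perfect_detection(self):
        g = component(box((0, 0, 0), (2, 2, 2)))
        assert lesion_f1(match_lesions([g], [g])) == 1.0

    def test_formula_arithmetic(self):
        # S_L = 1 (both gt detected), P_L = 0.5 (2 of 4 predictions matched)
        g1 = component(box((0, 0, 0), (2, 2, 2)))
        g2 = component(box((10, 10, 10), (2, 2, 2)))
        fp1 = component(box((20, 0, 0), (2, 2, 2)))
        fp2 = component(box((0, 20, 0), (2, 2, 2)))
        table = match_lesions([g1, g2], [g1, g2, fp1, fp2])
        assert lesion_f1(table) == pytest.approx(2 / 3)

    def test_no_gt_no_pred_is_undefined(self):
        assert lesion_f1(match_lesions([], [])) is None

    def test_no_gt_with_pred_is_zero(self):
        p = component(box((0, 0, 0), (2, 2, 2)))
        assert lesion_f1(match_lesions([], [p])) == 0.0

    def test_nothing_detected_is_zero(self):
        g = component(box((0, 0, 0), (2, 2, 2)))
        assert lesion_f1(match_lesions([g], [])) == 0.0


class TestFalsePositiveVolume:
    def test_no_predictions(self):
        assert false_positive_volume([]) == 0.0

    def test_single_component(self):
        assert false_positive_volume([component(box((0, 0, 0), (10, 1, 1)))]) == 10.0

    def test_spacing_scaling(self):
        vv = 0.5  # spacing (1, 1, 0.5)
        comps = [
            component(box((0, 0, 0), (4, 1, 1)), voxel_volume=vv),
            component(box((6, 0, 0), (6, 1, 1)), voxel_volume=vv),
        ]
        assert false_positive_volume(comps) == pytest.approx(5.0)

    def test_linear_in_voxel_volume(self):
        voxels = box((0, 0, 0), (3, 2, 1))
        for scale in (0.25, 1.0, 4.0):
            comps = [component(voxels, voxel_volume=scale)]
            assert false_positive_volume(comps) == pytest.approx(6 * scale)


class TestCohortEvaluate:
    def _perfect_pair(self, n_lesions, seed):
        data = np.zeros((24, 24, 24), np.uint8)
        rng = np.random.default_rng(seed)
        corners = rng.permutation(
            [(x, y, z) for x in range(1, 22, 4) for y in range(1, 22, 4) for z in range(1, 22, 4)]
        )[:n_lesions]
        for c in corners:
            data[c[0] : c[0] + 2, c[1] : c[1] + 2, c[2] : c[2] + 2] = 1
        m = LabelMask(data, (1, 1, 1))
        return (m, m)

    def test_perfect_predictions(self):
        pairs = [self._perfect_pair(3, s) for s in range(4)]
        report = cohort_evaluate(pairs)
        assert report.mean_dsc == 1.0
        assert report.mean_f1 == 1.0
        assert report.mean_n_fp == 0.0
        assert report.correctly_identified_new == 4

    def test_224_lesions_over_32_cases_mean_tp_is_7(self):
        pairs = [self._perfect_pair(7, s) for s in range(32)]
        report = cohort_evaluate(pairs)
        assert report.n_new_lesion_cases == 32
        assert report.mean_n_tp == 7.0

    def test_no_new_subset_averaging(self):
        empty = LabelMask(np.zeros((16, 16, 16), np.uint8), (1, 1, 1))
        fp = np.zeros((16, 16, 16), np.uint8)
        fp[2:4, 2:4, 2:4] = 1  # one 8 mm^3 false positive
        pairs = [(LabelMask(fp, (1, 1, 1)), empty)] + [(empty, empty)] * 3
        report = cohort_evaluate(pairs)
        assert report.n_no_new_lesion_cases == 4
        assert report.no_new_mean_n_fp == pytest.approx(1 / 4)
        assert report.no_new_mean_v_fp_mm3 == pytest.approx(8 / 4)
        assert report.correctly_identified_no_new == 3

    def test_subsets_partition_cohort(self):
        empty = LabelMask(np.zeros((16, 16, 16), np.uint8), (1, 1, 1))
        pairs = [self._perfect_pair(2, 0), (empty, empty)]
        report = cohort_evaluate(pairs)
        assert report.n_new_lesion_cases + report.n_no_new_lesion_cases == report.n_cases

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_evaluate([])

    def test_evaluate_case_subthreshold_gt_counts_as_no_new(self):
        gt = cube_mask((10, 10, 10), (4, 4, 4), 1)  # 1 mm^3 < 3 mm^3
        pred = LabelMask(np.zeros((10, 10, 10), np.uint8), (1, 1, 1))
        report = evaluate_case(pred, gt)
        assert not report.has_new_lesions_gt
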