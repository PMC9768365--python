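"""Mark-labeling rule semantics and the greedy one-to-one matching pass."""

from __future__ import annotations

import numpy as np
import pytest

from noduleval.data_model import Box2D, NoduleType, SliceAnnotation, ReferenceNodule
from noduleval.matching import (
    MatchOrder,
    MatchRule,
    RuleKind,
    box_center,
    match_case,
    match_case_scoped,
    matching_radius_mm,
    nodule_success,
    overlap_fraction,
    slice_success,
)

from conftest import UNIT, make_pred, make_ref, random_case
from oracle import brute_force_match

HIT = MatchRule(RuleKind.center_hit)
DIST = MatchRule(RuleKind.center_distance)
OVER = MatchRule(RuleKind.area_overlap)
ALL_RULES = [HIT, DIST, OVER]


class TestPrimitives:
    @pytest.mark.parametrize(
        "box,expected",
        [
            ((0, 0, 0, 10, 10), (5, 5)),
            ((0, 2, 4, 6, 8), (4, 6)),
            ((0, 0, 0, 1, 3), (0.5, 1.5)),
        ],
    )
    def test_box_center(self, box, expected):
        assert box_center(Box2D(*box)) == expected

    def test_overlap_fraction_is_relative_to_reference(self):
        ref = Box2D(0, 0, 0, 10, 10)
        assert overlap_fraction(ref, ref) == 1.0
        assert overlap_fraction(Box2D(0, 20, 20, 30, 30), ref) == 0.0
        assert overlap_fraction(Box2D(0, 5, 0, 15, 10), ref) == 0.5
        # ref contained in a bigger prediction still scores 1
        assert overlap_fraction(Box2D(0, -5, -5, 15, 15), ref) == 1.0

    def test_overlap_requires_same_slice(self):
        with pytest.raises(ValueError):
            overlap_fraction(Box2D(1, 0, 0, 5, 5), Box2D(2, 0, 0, 5, 5))

    def test_matching_radius_is_max_over_slices(self):
        slices = [
            SliceAnnotation(Box2D(1, 0, 0, 8, 6), 8, 6),
            SliceAnnotation(Box2D(2, 0, 0, 10, 6), 10, 6),
        ]
        ref = ReferenceNodule("c", "n", NoduleType.solid, slices, 7.0)
        assert matching_radius_mm(ref) == pytest.approx(4.0)
        single = make_ref("n", [(0, 0, 0, 4, 4)], long_d=4, short_d=4)
        assert matching_radius_mm(single) == pytest.approx(2.0)
        two = ReferenceNodule(
            "c", "n", NoduleType.solid,
            [SliceAnnotation(Box2D(1, 0, 0, 12, 8), 12, 8),
             SliceAnnotation(Box2D(2, 0, 0, 6, 2), 6, 2)], 7.0)
        assert matching_radius_mm(two) == pytest.approx(5.0)


class TestSliceSuccess:
    def test_center_hit_boundary_counts_as_inside(self):
        ref = make_ref("n", [(0, 0, 0, 10, 10)])
        ok, _ = slice_success(HIT, ref, ref.slices[0], Box2D(0, 0, 0, 10, 10), UNIT)
        assert ok
        # center exactly on the edge: (10, 5) from box (5,0,15,10)
        ok_edge, _ = slice_success(HIT, ref, ref.slices[0], Box2D(0, 5, 0, 15, 10), UNIT)
        assert ok_edge
        ok_out, _ = slice_success(HIT, ref, ref.slices[0], Box2D(0, 6, 0, 16, 10), UNIT)
        assert not ok_out

    def test_center_distance_threshold_is_strict(self):
        # radius = (8+8)/4 = 4 mm; center at (5,5)
        ref = make_ref("n", [(0, 0, 0, 10, 10)], long_d=8, short_d=8)
        at_3_99 = Box2D(0, 3.99, 0, 13.99, 10)  # center (8.99, 5): d = 3.99
        ok, score = slice_success(DIST, ref, ref.slices[0], at_3_99, UNIT)
        assert ok and score == pytest.approx(3.99)
        at_4 = Box2D(0, 4, 0, 14, 10)  # d = 4.0 exactly
        ok4, _ = slice_success(DIST, ref, ref.slices[0], at_4, UNIT)
        assert not ok4

    def test_area_overlap_threshold_is_strict(self):
        ref = make_ref("n", [(0, 0, 0, 10, 10)])
        exactly_half = Box2D(0, 5, 0, 15, 10)
        ok, score = slice_success(OVER, ref, ref.slices[0], exactly_half, UNIT)
        assert score == pytest.approx(0.5) and not ok
        just_over = Box2D(0, 4.9, 0, 14.9, 10)
        ok2, _ = slice_success(OVER, ref, ref.slices[0], just_over, UNIT)
        assert ok2

    def test_anisotropic_spacing_applies_per_axis(self):
        ref = make_ref("n", [(0, 0, 0, 10, 10)], long_d=8, short_d=8)
        # shift 3 px in x; spacing col=2 mm -> 6 mm > 4 mm radius
        shifted = Box2D(0, 3, 0, 13, 10)
        ok, score = slice_success(DIST, ref, ref.slices[0], shifted, (1.0, 2.0))
        assert score == pytest.approx(6.0) and not ok


class TestNoduleSuccess:
    def test_one_shared_slice_suffices(self):
        ref = make_ref("n", [(10, 0, 0, 10, 10), (11, 0, 0, 10, 10), (12, 0, 0, 10, 10)])
        pred = make_pred("p", [(9, 2, 2, 8, 8), (10, 2, 2, 8, 8)])
        ok, _ = nodule_success(HIT, ref, pred, UNIT)
        assert ok

    def test_no_shared_slice_fails(self):
        ref = make_ref("n", [(10, 0, 0, 10, 10), (11, 0, 0, 10, 10)])
        pred = make_pred("p", [(1, 0, 0, 10, 10), (2, 0, 0, 10, 10)])
        ok, score = nodule_success(HIT, ref, pred, UNIT)
        assert not ok and score is None

    def test_best_score_is_minimum_distance(self):
        ref = make_ref("n", [(10, 0, 0, 10, 10), (11, 0, 0, 10, 10)], long_d=8, short_d=8)
        # slice 10 offset by 1.2 mm, slice 11 offset by 0.7 mm
        pred = make_pred("p", [(10, 1.2, 0, 11.2, 10), (11, 0.7, 0, 10.7, 10)])
        ok, score = nodule_success(DIST, ref, pred, UNIT)
        assert ok and score == pytest.approx(0.7)


class TestMatchCase:
    def test_perfect_single_detection(self):
        ref = make_ref("n1", [(5, 10, 10, 20, 20)])
        pred = make_pred("p1", [(5, 10, 10, 20, 20)])
        for rule in ALL_RULES:
            res = match_case([ref], [pred], rule, UNIT)
            assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_matching_order_gives_pred_to_first_reference(self):
        # r1 has the larger largest-slice area so it is matched first
        r1 = make_ref("r1", [(5, 0, 0, 20, 20)])
        r2 = make_ref("r2", [(5, 5, 5, 18, 18)])
        pred = make_pred("p1", [(5, 6, 6, 17, 17)])  # satisfies both
        res = match_case([r2, r1], [pred], HIT, UNIT)
        assert res.matched_pred_of == {"r1": "p1"}
        assert res.fn_ids == ["r2"]

    def test_closest_of_two_candidates_wins_and_other_becomes_fp(self):
        ref = make_ref("n1", [(5, 0, 0, 10, 10)], long_d=8, short_d=8)
        far = make_pred("p_far", [(5, 2, 0, 12, 10)])  # center distance 2.0
        near = make_pred("p_near", [(5, 1, 0, 11, 10)])  # center distance 1.0
        res = match_case([ref], [far, near], DIST, UNIT)
        assert res.matched_pred_of == {"n1": "p_near"}
        assert res.fp_ids == ["p_far"]

    def test_score_tie_resolved_to_lowest_pred_id(self):
        ref = make_ref("n1", [(5, 0, 0, 10, 10)], long_d=8, short_d=8)
        left = make_pred("pb", [(5, -1, 0, 9, 10)])
        right = make_pred("pa", [(5, 1, 0, 11, 10)])  # same distance 1.0
        res = match_case([ref], [left, right], DIST, UNIT)
        assert res.matched_pred_of == {"n1": "pa"}

    def test_mixed_case_ids_rejected(self):
        r = make_ref("n1", [(0, 0, 0, 5, 5)], case_id="a")
        p = make_pred("p1", [(0, 0, 0, 5, 5)], case_id="b")
        with pytest.raises(ValueError, match="mixed case_ids"):
            match_case([r], [p], HIT, UNIT)

    def test_center_hit_tiebreak_uses_largest_reference_slice(self):
        # largest slice at index 6; p_far is closer on slice 5 but farther on 6
        ref = make_ref("n1", [(5, 0, 0, 10, 10), (6, -5, -5, 15, 15)])
        p_a = make_pred("pa", [(5, 1, 1, 9, 9), (6, 3, 3, 13, 13)])
        p_b = make_pred("pb", [(5, 3, 3, 13, 13), (6, 1, 1, 9, 9)])
        res = match_case([ref], [p_a, p_b], HIT, UNIT)
        assert res.matched_pred_of == {"n1": "pb"}


class TestProperties:
    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.kind.value)
    def test_conservation_and_one_to_one(self, rule, rng):
        for _ in range(400):
            refs, preds = random_case(rng, int(rng.integers(0, 5)), int(rng.integers(0, 5)))
            res = match_case(refs, preds, rule, UNIT)
            assert res.tp + res.fn == len(refs)
            assert res.tp + res.fp == len(preds)
            ref_ids = [nid for nid, _, _ in res.assignments] + res.fn_ids
            pred_ids = [pid for _, pid, _ in res.assignments] + res.fp_ids
            assert len(ref_ids) == len(set(ref_ids))
            assert len(pred_ids) == len(set(pred_ids))

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.kind.value)
    def test_equals_brute_force_flowchart_trace(self, rule, rng):
        from noduleval.matching import order_references

        for _ in range(400):
            refs, preds = random_case(rng, int(rng.integers(1, 5)), int(rng.integers(0, 5)))
            ordered = order_references(refs)
            res = match_case(refs, preds, rule, UNIT)
            oracle_assign, oracle_fn, oracle_fp = brute_force_match(
                ordered, preds, rule.kind.value, UNIT, rule.overlap_threshold
            )
            assert res.matched_pred_of == oracle_assign
            assert sorted(res.fn_ids) == sorted(oracle_fn)
            assert sorted(res.fp_ids) == sorted(oracle_fp)

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.kind.value)
    def test_adding_prediction_never_decreases_tp(self, rule, rng):
        for _ in range(150):
            refs, preds = random_case(rng, 3, 3)
            extra_refs, extra_preds = random_case(rng, 0, 1)
            extra = make_pred("zz_extra", [(b.slice_index, b.x_min, b.y_min, b.x_max, b.y_max)
                                           for b in extra_preds[0].boxes])
            before = match_case(refs, preds, rule, UNIT).tp
            after = match_case(refs, preds + [extra], rule, UNIT).tp
            assert after >= before

    @pytest.mark.parametrize("rule", ALL_RULES, ids=lambda r: r.kind.value)
    def test_removing_reference_never_increases_fn(self, rule, rng):
        for _ in range(150):
            refs, preds = random_case(rng, 4, 3)
            before = match_case(refs, preds, rule, UNIT).fn
            after = match_case(refs[:-1], preds, rule, UNIT).fn
            assert after <= before

    def test_all_rules_agree_on_perfect_disjoint_predictions(self, rng):
        refs, preds = [], []
        for i in range(4):
            x = 5 + 22 * i
            boxes = [(3, x, 5.0, x + 12, 17.0), (4, x, 5.0, x + 12, 17.0)]
            refs.append(make_ref(f"n{i}", boxes, long_d=9, short_d=7))
            preds.append(make_pred(f"p{i}", boxes))
        for rule in ALL_RULES:
            res = match_case(refs, preds, rule, UNIT)
            assert (res.tp, res.fp, res.fn) == (4, 0, 0)


class TestTypeScope:
    def test_out_of_scope_reference_leaves_accounting(self):
        solid = make_ref("n1", [(5, 0, 0, 10, 10)])
        pleural = make_ref("n2", [(5, 40, 40, 50, 50)], ntype=NoduleType.pleural)
        p_solid = make_pred("p1", [(5, 0, 0, 10, 10)])
        p_pleural = make_pred("p2", [(5, 40, 40, 50, 50)])
        scope = [NoduleType.solid]
        res = match_case_scoped([solid, pleural], [p_solid, p_pleural], HIT, UNIT,
                                type_scope=scope)
        # pleural ref excluded; its matching prediction dropped, not FP
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_unrelated_prediction_still_counts_fp_under_scope(self):
        solid = make_ref("n1", [(5, 0, 0, 10, 10)])
        pleural = make_ref("n2", [(5, 40, 40, 50, 50)], ntype=NoduleType.pleural)
        stray = make_pred("p9", [(5, 80, 80, 90, 90)])
        res = match_case_scoped([solid, pleural], [stray], HIT, UNIT,
                                type_scope=[NoduleType.solid])
        assert (res.tp, res.fp, res.fn) == (0, 1, 1)

    def test_none_scope_keeps_everything(self):
        refs, preds = random_case(np.random.default_rng(5), 3, 3)
        full = match_case(refs, preds, HIT, UNIT)
        scoped = match_case_scoped(refs, preds, HIT, UNIT, type_scope=None)
        assert full.matched_pred_of == scoped.matched_pred_of
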