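"""Mark-labeling rules and greedy one-to-one matching of predictions to references.

Three rules decide whether a predicted bounding-box stack detects a reference
nodule, evaluated per shared slice:

* ``center_hit`` — the predicted box center lies inside the reference box
  (closed region; the boundary counts as inside);
* ``center_distance`` — the in-plane center distance in mm is strictly below
  an adaptive per-nodule threshold, the maximum over slices of
  (long + short diameter)/4;
* ``area_overlap`` — the intersection area divided by the *reference* box
  area is strictly above a threshold (default 0.5).

A multi-slice prediction detects a multi-slice reference as soon as one
shared slice succeeds. Matching is greedy and order-driven: references are
walked in a canonical order (largest-slice area descending by default), each
taking its best remaining candidate; a prediction consumed by one reference
cannot match another. Leftover references are false negatives, leftover
predictions false positives.

Inequalities at the thresholds are strict by design: a center distance equal
to the radius, or an overlap fraction equal to the threshold, is a failure.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .data_model import (
    Box2D,
    NoduleType,
    PredictedNodule,
    ReferenceNodule,
    SliceAnnotation,
)

__all__ = [
    "RuleKind",
    "MatchRule",
    "MatchResult",
    "MatchOrder",
    "box_center",
    "overlap_fraction",
    "matching_radius_mm",
    "slice_success",
    "nodule_success",
    "match_case",
    "match_case_scoped",
    "order_references",
]


class RuleKind(str, enum.Enum):
    center_hit = "center_hit"
    center_distance = "center_distance"
    area_overlap = "area_overlap"

    def __str__(self) -> str:
        return self.value


class MatchOrder(str, enum.Enum):
    """Order in which references claim candidates: file order, size, or id."""

    file = "file"
    size = "size"  # largest-slice box area descending, then nodule_id
    id = "id"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class MatchRule:
    kind: RuleKind
    overlap_threshold: float = 0.5  # used only by area_overlap

    def __post_init__(self) -> None:
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")


@dataclass
class MatchResult:
    """One-to-one assignment plus FN/FP sets for one case under one rule."""

    rule: MatchRule
    assignments: list[tuple[str, str, float]] = field(default_factory=list)
    fn_ids: list[str] = field(default_factory=list)
    fp_ids: list[str] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.assignments)

    @property
    def fn(self) -> int:
        return len(self.fn_ids)

    @property
    def fp(self) -> int:
        return len(self.fp_ids)

    @property
    def matched_pred_of(self) -> dict[str, str]:
        return {nid: pid for nid, pid, _ in self.assignments}


def box_center(box: Box2D) -> tuple[float, float]:
    """Midpoint of the box on each axis, in pixels."""
    return box.center


def overlap_fraction(pred: Box2D, ref: Box2D) -> float:
    """Intersection area over the reference box area, in [0, 1]."""
    if pred.slice_index != ref.slice_index:
        raise ValueError("overlap_fraction requires boxes on the same slice")
    w = min(pred.x_max, ref.x_max) - max(pred.x_min, ref.x_min)
    h = min(pred.y_max, ref.y_max) - max(pred.y_min, ref.y_min)
    if w <= 0 or h <= 0:
        return 0.0
    return (w * h) / ref.area


def matching_radius_mm(ref: ReferenceNodule) -> float:
    """Adaptive center-distance threshold: max over slices of (long+short)/4 mm."""
    return ref.matching_radius_mm


def center_distance_mm(
    a: Box2D, b: Box2D, spacing: tuple[float, float]
) -> float:
    """In-plane Euclidean distance between box centers, anisotropic spacing in mm.

    ``spacing`` is (row, col) mm per pixel, i.e. (y, x).
    """
    (ax, ay), (bx, by) = a.center, b.center
    dy = (ay - by) * spacing[0]
    dx = (ax - bx) * spacing[1]
    return math.hypot(dx, dy)


def slice_success(
    rule: MatchRule,
    ref: ReferenceNodule,
    ref_slice: SliceAnnotation,
    pred_box: Box2D,
    spacing: tuple[float, float],
) -> tuple[bool, float]:
    """Evaluate one rule on one shared slice.

    Returns ``(success, tiebreak_score)`` where the score is the in-plane
    center distance in mm (center_hit, center_distance) or the overlap
    fraction (area_overlap).
    """
    if ref_slice.box.slice_index != pred_box.slice_index:
        raise ValueError("slice_success requires boxes on the same slice")
    if rule.kind is RuleKind.center_hit:
        cx, cy = pred_box.center
        ok = ref_slice.box.contains_point(cx, cy)
        return ok, center_distance_mm(pred_box, ref_slice.box, spacing)
    if rule.kind is RuleKind.center_distance:
        d = center_distance_mm(pred_box, ref_slice.box, spacing)
        return d < ref.matching_radius_mm, d
    frac = overlap_fraction(pred_box, ref_slice.box)
    return frac > rule.overlap_threshold, frac


def nodule_success(
    rule: MatchRule,
    ref: ReferenceNodule,
    pred: PredictedNodule,
    spacing: tuple[float, float],
) -> tuple[bool, float | None]:
    """Whether the prediction detects the reference on at least one shared slice.

    The best score over succeeding slice pairs is the minimum distance for
    the center rules and the maximum overlap fraction for the overlap rule.
    Zero shared slices is a failure (score None).
    """
    ref_slices = ref.slice_map()
    best: float | None = None
    maximize = rule.kind is RuleKind.area_overlap
    for pb in pred.boxes:
        rs = ref_slices.get(pb.slice_index)
        if rs is None:
            continue
        ok, score = slice_success(rule, ref, rs, pb, spacing)
        if not ok:
            continue
        if best is None or (score > best if maximize else score < best):
            best = score
    return best is not None, best


def order_references(
    refs: Sequence[ReferenceNodule], order: MatchOrder = MatchOrder.size
) -> list[ReferenceNodule]:
    """Canonical matching order for a case's reference nodules.

    Default ``size``: descending largest-slice box area, ties by ascending
    nodule_id — a large nodule claims its candidate before a small neighbor
    can consume it, and the order is deterministic.
    """
    if order is MatchOrder.file:
        return list(refs)
    if order is MatchOrder.id:
        return sorted(refs, key=lambda r: r.nodule_id)
    return sorted(refs, key=lambda r: (-r.largest_slice.box.area, r.nodule_id))


def _center_hit_tiebreak(
    ref: ReferenceNodule, pred: PredictedNodule, spacing: tuple[float, float]
) -> float:
    """Tiebreak among multiple hitting candidates: in-plane center distance to
    the reference's largest slice, measured on the candidate's box at that
    slice index if present, else at the candidate's slice nearest to it."""
    target = ref.largest_slice.box
    boxes = pred.box_map()
    if target.slice_index in boxes:
        pb = boxes[target.slice_index]
    else:
        nearest = min(boxes, key=lambda i: (abs(i - target.slice_index), i))
        pb = boxes[nearest]
    return center_distance_mm(pb, target, spacing)


def match_case(
    refs: Sequence[ReferenceNodule],
    preds: Sequence[PredictedNodule],
    rule: MatchRule,
    spacing: tuple[float, float],
    order: MatchOrder = MatchOrder.size,
) -> MatchResult:
    """Greedy one-to-one matching for a single case.

    References are processed in the canonical order. For each, the candidates
    are the still-unmatched predictions that detect it; if none it is a false
    negative, otherwise the candidate with the best tiebreak score is
    assigned and removed from the pool. After the pass, unmatched predictions
    are false positives. Candidates tied on the score are resolved to the
    lowest pred_id.
    """
    case_ids = {r.case_id for r in refs} | {p.case_id for p in preds}
    if len(case_ids) > 1:
        raise ValueError(f"match_case called with mixed case_ids: {sorted(case_ids)}")

    ordered = order_references(refs, order)
    pool: dict[str, PredictedNodule] = {p.pred_id: p for p in preds}
    if len(pool) != len(preds):
        raise ValueError("duplicate pred_id within case")
    result = MatchResult(rule=rule)

    for ref in ordered:
        candidates: list[tuple[float, str]] = []
        for pid, pred in pool.items():
            ok, score = nodule_success(rule, ref, pred, spacing)
            if not ok:
                continue
            if rule.kind is RuleKind.center_hit:
                score = _center_hit_tiebreak(ref, pred, spacing)
            candidates.append((score, pid))
        if not candidates:
            result.fn_ids.append(ref.nodule_id)
            continue
        if rule.kind is RuleKind.area_overlap:
            best_score, best_pid = max(
                candidates, key=lambda c: (c[0], _neg_id_key(c[1]))
            )
        else:
            best_score, best_pid = min(candidates, key=lambda c: (c[0], c[1]))
        result.assignments.append((ref.nodule_id, best_pid, best_score))
        del pool[best_pid]

    result.fp_ids.extend(sorted(pool))
    return result


class _neg_id_key:
    """Reverses lexicographic order so max() prefers the *lowest* pred_id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_id_key") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id_key) and self.s == other.s


def match_case_scoped(
    refs: Sequence[ReferenceNodule],
    preds: Sequence[PredictedNodule],
    rule: MatchRule,
    spacing: tuple[float, float],
    order: MatchOrder = MatchOrder.size,
    type_scope: Iterable[NoduleType] | None = None,
) -> MatchResult:
    """Match with an optional restriction to an AUT's declared detectable types.

    References outside the scope leave TP/FN accounting entirely. Leftover
    predictions are then matched against the excluded references, and any
    that match are dropped rather than counted as false positives (an AUT not
    designed for pleural nodules is not penalized for finding one).
    ``type_scope=None`` (the default) scores all six types.
    """
    if type_scope is None:
        return match_case(refs, preds, rule, spacing, order)
    scope_set = set(type_scope)
    in_scope = [r for r in refs if r.type in scope_set]
    out_scope = [r for r in refs if r.type not in scope_set]
    result = match_case(in_scope, preds, rule, spacing, order)
    if out_scope and result.fp_ids:
        leftovers = [p for p in preds if p.pred_id in set(result.fp_ids)]
        shadow = match_case(out_scope, leftovers, rule, spacing, order)
        consumed = {pid for _, pid, _ in shadow.assignments}
        result.fp_ids = [pid for pid in result.fp_ids if pid not in consumed]
    return result
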