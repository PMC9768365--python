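"""Annotator qualification scoring and three-reader consensus merging.

Reference-standard construction uses teams of three junior radiologists who
annotate the same cases independently. A candidate annotator qualifies by
matching an expert panel's annotations with precision, recall and Dice all
strictly above 0.8. During production annotation, the three readers' outputs
are merged automatically: a nodule detected consistently by all three is
kept (geometry = per-slice union of the three readers' regions), while any
slice carrying a detection the readers do not all share is flagged for
senior-expert arbitration.

"Consistent" is operationalized as mutual pairwise matching between all
three readers under a configurable mark-labeling rule (default center hit).
Dice is computed on the annotated boundary polygons when present and on the
bounding boxes otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from shapely.geometry import Polygon, box as shapely_box
from shapely.ops import unary_union

from .data_model import (
    Box2D,
    PredictedNodule,
    ReferenceNodule,
    SliceAnnotation,
)
from .matching import MatchRule, RuleKind, match_case

__all__ = [
    "QualificationResult",
    "ConsensusOutput",
    "dice_coefficient",
    "qualify_annotator",
    "consensus_merge",
    "as_prediction",
]

_DEFAULT_RULE = MatchRule(RuleKind.center_hit)
_UNIT_SPACING = (1.0, 1.0)


@dataclass(frozen=True)
class QualificationResult:
    precision: float
    recall: float
    dice: float

    @property
    def passed(self) -> bool:
        """All three criteria are strict: exactly 0.8 on any of them fails."""
        return self.precision > 0.8 and self.recall > 0.8 and self.dice > 0.8


@dataclass
class ConsensusOutput:
    merged: list[ReferenceNodule]
    flagged_slices: list[tuple[str, int]]


def _slice_geometry(s: SliceAnnotation):
    if s.boundary is not None:
        return Polygon(s.boundary)
    b = s.box
    return shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)


def _region_map(nodule: ReferenceNodule) -> dict[int, object]:
    return {s.box.slice_index: _slice_geometry(s) for s in nodule.slices}


def dice_coefficient(region_a: ReferenceNodule, region_b: ReferenceNodule) -> float:
    """Dice agreement 2|A∩B| / (|A|+|B|) between two annotated nodules.

    Intersection areas are accumulated over shared slices; each region's own
    area over all of its slices. Boundary polygons are used where annotated,
    bounding boxes otherwise.
    """
    a_map, b_map = _region_map(region_a), _region_map(region_b)
    area_a = sum(g.area for g in a_map.values())
    area_b = sum(g.area for g in b_map.values())
    if area_a + area_b == 0:
        raise ZeroDivisionError("Dice undefined: both regions empty")
    inter = sum(
        a_map[i].intersection(b_map[i]).area for i in a_map.keys() & b_map.keys()
    )
    return 2.0 * inter / (area_a + area_b)


def as_prediction(nodule: ReferenceNodule) -> PredictedNodule:
    """View an annotated nodule as a bounding-box stack for matching."""
    return PredictedNodule(
        case_id=nodule.case_id,
        pred_id=nodule.nodule_id,
        boxes=[s.box for s in nodule.slices],
    )


def qualify_annotator(
    candidate: Mapping[str, Sequence[ReferenceNodule]],
    expert: Mapping[str, Sequence[ReferenceNodule]],
    rule: MatchRule = _DEFAULT_RULE,
    spacing_by_case: Mapping[str, tuple[float, float]] | None = None,
) -> QualificationResult:
    """Score a candidate annotator against the expert panel, per nodule.

    Candidate annotations are matched to expert nodules case by case under
    the given rule; precision and recall are detection counts pooled over
    cases, and Dice is the mean over matched pairs.
    """
    if not any(expert.values()):
        raise ValueError("expert annotation set is empty")
    tp = fp = fn = 0
    dices: list[float] = []
    for case_id in sorted(set(expert) | set(candidate)):
        refs = list(expert.get(case_id, []))
        cand = {n.nodule_id: n for n in candidate.get(case_id, [])}
        preds = [as_prediction(n) for n in cand.values()]
        spacing = (
            spacing_by_case.get(case_id, _UNIT_SPACING)
            if spacing_by_case
            else _UNIT_SPACING
        )
        res = match_case(refs, preds, rule, spacing)
        tp += res.tp
        fp += res.fp
        fn += res.fn
        ref_by_id = {n.nodule_id: n for n in refs}
        for nid, pid, _ in res.assignments:
            dices.append(dice_coefficient(cand[pid], ref_by_id[nid]))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    dice = sum(dices) / len(dices) if dices else 0.0
    return QualificationResult(precision=precision, recall=recall, dice=dice)


def _merge_group(members: Sequence[ReferenceNodule]) -> ReferenceNodule:
    """Union geometry of a consistent reader group, one slice at a time."""
    per_slice: dict[int, list[SliceAnnotation]] = {}
    for m in members:
        for s in m.slices:
            per_slice.setdefault(s.box.slice_index, []).append(s)
    slices = []
    for idx in sorted(per_slice):
        anns = per_slice[idx]
        union = unary_union([_slice_geometry(s) for s in anns])
        x0, y0, x1, y1 = union.bounds
        long_d = max(s.long_diameter_mm for s in anns)
        short_d = min(max(s.short_diameter_mm for s in anns), long_d)
        slices.append(
            SliceAnnotation(
                box=Box2D(idx, x0, y0, x1, y1),
                long_diameter_mm=long_d,
                short_diameter_mm=short_d,
            )
        )
    # reader-order-invariant identity and majority type (ties -> stable value order)
    merged_id = "+".join(sorted(m.nodule_id for m in members))
    counts = Counter(m.type for m in members)
    top = max(counts.values())
    merged_type = sorted(t.value for t, c in counts.items() if c == top)[0]
    avg_d = sum(m.average_diameter_mm for m in members) / len(members)
    return ReferenceNodule(
        case_id=members[0].case_id,
        nodule_id=merged_id,
        type=type(members[0].type)(merged_type),
        slices=slices,
        average_diameter_mm=avg_d,
    )


def consensus_merge(
    readers: Sequence[Sequence[ReferenceNodule]],
    rule: MatchRule = _DEFAULT_RULE,
    spacing: tuple[float, float] = _UNIT_SPACING,
) -> ConsensusOutput:
    """Merge three readers' annotations for one case.

    Nodules are grouped by pairwise matching between every reader pair; a
    group is consistent when it contains exactly one nodule from each reader
    and every pair matched mutually. Consistent groups are merged to their
    per-slice union; every slice of every other detection is flagged as
    (case_id, slice_index) for arbitration.
    """
    if len(readers) != 3:
        raise ValueError(f"consensus_merge requires exactly 3 readers, got {len(readers)}")
    case_ids = {n.case_id for r in readers for n in r}
    if len(case_ids) > 1:
        raise ValueError(f"readers annotate different cases: {sorted(case_ids)}")

    # nodes keyed by (reader_index, nodule_id)
    nodes = {
        (i, n.nodule_id): n for i, reader in enumerate(readers) for n in reader
    }
    edges: set[frozenset] = set()
    for i in range(3):
        for j in range(i + 1, 3):
            res = match_case(
                list(readers[i]),
                [as_prediction(n) for n in readers[j]],
                rule,
                spacing,
            )
            for nid, pid, _ in res.assignments:
                edges.add(frozenset({(i, nid), (j, pid)}))

    # connected components over the match graph
    parent = {k: k for k in nodes}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for e in edges:
        a, b = tuple(e)
        parent[find(a)] = find(b)

    components: dict = {}
    for k in nodes:
        components.setdefault(find(k), []).append(k)

    merged: list[ReferenceNodule] = []
    flagged: set[tuple[str, int]] = set()
    for comp in components.values():
        readers_in = {k[0] for k in comp}
        is_triangle = (
            len(comp) == 3
            and readers_in == {0, 1, 2}
            and all(
                frozenset({a, b}) in edges
                for x, a in enumerate(comp)
                for b in comp[x + 1:]
            )
        )
        members = [nodes[k] for k in comp]
        if is_triangle:
            merged.append(_merge_group(members))
        else:
            for m in members:
                for s in m.slices:
                    flagged.add((m.case_id, s.box.slice_index))
    merged.sort(key=lambda n: n.nodule_id)
    return ConsensusOutput(merged=merged, flagged_slices=sorted(flagged))
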