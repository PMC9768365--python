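"""Brute-force matching oracle, independent of the package's matching code.

Walks the matching flowchart literally: every reference nodule, in the
given order, scans the full queue of still-unmatched predictions, computes
rule success from raw geometry (re-derived here from scratch), and claims
the best-scoring candidate. Used only to cross-check match_case.
"""

from __future__ import annotations

import math


def _center(box):
    return ((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


def _dist_mm(box_a, box_b, spacing):
    (ax, ay), (bx, by) = _center(box_a), _center(box_b)
    return math.sqrt(((ax - bx) * spacing[1]) ** 2 + ((ay - by) * spacing[0]) ** 2)


def _overlap_over_ref(pred, ref):
    w = min(pred.x_max, ref.x_max) - max(pred.x_min, ref.x_min)
    h = min(pred.y_max, ref.y_max) - max(pred.y_min, ref.y_min)
    if w <= 0 or h <= 0:
        return 0.0
    ref_area = (ref.x_max - ref.x_min) * (ref.y_max - ref.y_min)
    return w * h / ref_area


def _radius_mm(ref):
    return max((s.long_diameter_mm + s.short_diameter_mm) / 4.0 for s in ref.slices)


def _largest_slice_box(ref):
    best = None
    for s in ref.slices:
        area = (s.box.x_max - s.box.x_min) * (s.box.y_max - s.box.y_min)
        if best is None or area > best[0]:
            best = (area, s.box)
    return best[1]


def _succeeds(rule_kind, overlap_threshold, ref, pred, spacing):
    """(success, score) for a ref/pred pair, all slices paired by equal index."""
    ref_boxes = {s.box.slice_index: s.box for s in ref.slices}
    scores = []
    for pb in pred.boxes:
        rb = ref_boxes.get(pb.slice_index)
        if rb is None:
            continue
        if rule_kind == "center_hit":
            cx, cy = _center(pb)
            if rb.x_min <= cx <= rb.x_max and rb.y_min <= cy <= rb.y_max:
                scores.append(_dist_mm(pb, rb, spacing))
        elif rule_kind == "center_distance":
            d = _dist_mm(pb, rb, spacing)
            if d < _radius_mm(ref):
                scores.append(d)
        else:  # area_overlap
            f = _overlap_over_ref(pb, rb)
            if f > overlap_threshold:
                scores.append(f)
    if not scores:
        return False, None
    return True, (max(scores) if rule_kind == "area_overlap" else min(scores))


def _hit_tiebreak(ref, pred, spacing):
    target = _largest_slice_box(ref)
    by_idx = {b.slice_index: b for b in pred.boxes}
    if target.slice_index in by_idx:
        pb = by_idx[target.slice_index]
    else:
        nearest = min(by_idx, key=lambda i: (abs(i - target.slice_index), i))
        pb = by_idx[nearest]
    return _dist_mm(pb, target, spacing)


def brute_force_match(refs_in_order, preds, rule_kind, spacing, overlap_threshold=0.5):
    """Explicit queue walk-through of the matching flowchart.

    Returns (assignments {nodule_id: pred_id}, fn_ids, fp_ids).
    """
    queue = list(preds)
    assignments = {}
    fn = []
    for ref in refs_in_order:
        candidates = []
        for p in queue:
            ok, score = _succeeds(rule_kind, overlap_threshold, ref, p, spacing)
            if not ok:
                continue
            tb = _hit_tiebreak(ref, p, spacing) if rule_kind == "center_hit" else score
            candidates.append((tb, p))
        if not candidates:
            fn.append(ref.nodule_id)
            continue
        if rule_kind == "area_overlap":
            best_tb = max(tb for tb, _ in candidates)
        else:
            best_tb = min(tb for tb, _ in candidates)
        tied = sorted(p.pred_id for tb, p in candidates if tb == best_tb)
        winner = tied[0]
        assignments[ref.nodule_id] = winner
        queue = [p for p in queue if p.pred_id != winner]
    fp = sorted(p.pred_id for p in queue)
    return assignments, fn, fp
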