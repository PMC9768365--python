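"""Detection metrics, per-AUT aggregation and stratified miss-rate analysis.

Counts are pooled over cases before ratios are formed (micro-averaging), so
an AUT's recall is TP / (TP + FN) over the whole test set. The summary over
a panel of AUTs is the mean ± sample standard deviation of the per-AUT
pooled metrics. Zero-denominator ratios follow the documented convention:
0/0 → 0 for recall/precision, and F1 is 0 when precision + recall is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import NoduleType, ReferenceNodule, SizeBin, size_bin_of
from .matching import MatchResult

__all__ = [
    "MetricSet",
    "compute_metrics",
    "aggregate_over_auts",
    "rule_delta",
    "relative_difference",
    "miss_rate_by_type",
    "miss_rate_by_type_and_bin",
    "most_missed_per_bin",
]


@dataclass(frozen=True)
class MetricSet:
    """Raw detection counts with recall / precision / F1."""

    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }


def compute_metrics(results: Mapping[str, MatchResult]) -> MetricSet:
    """Pool per-case match results (keyed by case_id) for one AUT and one rule."""
    tp = sum(r.tp for r in results.values())
    fp = sum(r.fp for r in results.values())
    fn = sum(r.fn for r in results.values())
    return MetricSet(tp=tp, fp=fp, fn=fn)


def aggregate_over_auts(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of per-AUT metric values."""
    if len(values) < 2:
        raise ValueError("aggregate_over_auts needs >= 2 per-AUT values")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def rule_delta(
    means_a: Mapping[str, float], means_b: Mapping[str, float]
) -> dict[str, float]:
    """Signed per-metric differences a - b in percentage points, 2 decimals.

    Inputs are mean metric values on the percent scale (e.g. recall 54.68).
    """
    return {
        k: round(means_a[k] - means_b[k], 2) for k in means_a if k in means_b
    }


def relative_difference(tp_compared: int, tp_baseline: int) -> float:
    """Relative difference of TP counts against a baseline rule.

    rd = (TP_compared - TP_baseline) / TP_baseline. The paper-style usage
    takes center hit as the baseline, so a positive value means the compared
    rule credits more detections.
    """
    if tp_baseline <= 0:
        raise ZeroDivisionError("relative difference undefined for zero baseline TP")
    return (tp_compared - tp_baseline) / tp_baseline


def _fn_counts_by_key(
    results: Mapping[str, MatchResult],
    references: Mapping[str, Sequence[ReferenceNodule]],
    key,
) -> tuple[dict, dict]:
    """FN and reference totals per stratum key for one AUT."""
    n_ref: dict = {}
    n_fn: dict = {}
    for case_id, refs in references.items():
        res = results.get(case_id)
        fn_ids = set(res.fn_ids) if res is not None else {r.nodule_id for r in refs}
        for r in refs:
            k = key(r)
            n_ref[k] = n_ref.get(k, 0) + 1
            if r.nodule_id in fn_ids:
                n_fn[k] = n_fn.get(k, 0) + 1
    return n_fn, n_ref


def miss_rate_by_type(
    results_by_aut: Mapping[str, Mapping[str, MatchResult]],
    references: Mapping[str, Sequence[ReferenceNodule]],
) -> dict[NoduleType, dict[str, float | None]]:
    """Per-type miss rate (FN / reference count) for each AUT, with mean ± SD.

    Returns ``{type: {aut: rate..., "mean": m, "sd": s}}``. A type with no
    reference nodules yields None cells (undefined, never zero).
    """
    table: dict[NoduleType, dict[str, float | None]] = {
        t: {} for t in NoduleType
    }
    for aut, results in results_by_aut.items():
        n_fn, n_ref = _fn_counts_by_key(results, references, key=lambda r: r.type)
        for t in NoduleType:
            denom = n_ref.get(t, 0)
            table[t][aut] = (n_fn.get(t, 0) / denom) if denom else None
    for t, row in table.items():
        vals = [v for v in row.values() if v is not None]
        if len(vals) >= 2:
            m, s = aggregate_over_auts(vals)
        elif len(vals) == 1:
            m, s = vals[0], None
        else:
            m = s = None
        row["mean"] = m
        row["sd"] = s
    return table


def miss_rate_by_type_and_bin(
    results: Mapping[str, MatchResult],
    references: Mapping[str, Sequence[ReferenceNodule]],
) -> dict[tuple[NoduleType, SizeBin], float | None]:
    """Per (type, size-bin) miss rate for a single AUT; None when undefined."""
    n_fn, n_ref = _fn_counts_by_key(
        results, references, key=lambda r: (r.type, size_bin_of(r.average_diameter_mm))
    )
    out: dict[tuple[NoduleType, SizeBin], float | None] = {}
    for t in NoduleType:
        for b in SizeBin:
            denom = n_ref.get((t, b), 0)
            out[(t, b)] = (n_fn.get((t, b), 0) / denom) if denom else None
    return out


def most_missed_per_bin(
    results_by_aut: Mapping[str, Mapping[str, MatchResult]],
    references: Mapping[str, Sequence[ReferenceNodule]],
) -> tuple[dict[SizeBin, dict[NoduleType, int]], list[tuple[str, SizeBin]]]:
    """Heatmap counts: per size bin, how many AUTs miss each type the most.

    For each AUT and bin, the type with the highest defined miss rate
    contributes one count; exact ties credit every tied type, and the
    (aut, bin) pair is reported in the returned tie list. Bins with no
    reference nodules are excluded.
    """
    heat: dict[SizeBin, dict[NoduleType, int]] = {
        b: {t: 0 for t in NoduleType} for b in SizeBin
    }
    ties: list[tuple[str, SizeBin]] = []
    for aut, results in results_by_aut.items():
        rates = miss_rate_by_type_and_bin(results, references)
        for b in SizeBin:
            defined = {
                t: rates[(t, b)] for t in NoduleType if rates[(t, b)] is not None
            }
            if not defined:
                continue
            worst = max(defined.values())
            winners = [t for t, v in defined.items() if v == worst]
            for t in winners:
                heat[b][t] += 1
            if len(winners) > 1:
                ties.append((aut, b))
    return heat, ties


def overall_fn_consistency(
    results: Mapping[str, MatchResult],
    references: Mapping[str, Sequence[ReferenceNodule]],
) -> bool:
    """Overall FN count equals the sum over types of per-type FN counts."""
    n_fn, _ = _fn_counts_by_key(results, references, key=lambda r: r.type)
    return sum(n_fn.values()) == sum(r.fn for r in results.values())


def percent(x: float) -> float:
    """Convenience: fraction → percent rounded the way reports print it."""
    return round(100.0 * x, 2)
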