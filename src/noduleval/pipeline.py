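"""End-to-end evaluation drivers: evaluate, compare rules, error analysis.

These functions tie the matching, metrics and stats layers together over
whole datasets (references + one prediction set per AUT + per-case
geometry) and produce the report structures the CLI serializes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .data_model import CaseRecord, NoduleType, PredictedNodule, ReferenceNodule
from .matching import (
    MatchOrder,
    MatchResult,
    MatchRule,
    RuleKind,
    match_case_scoped,
)
from .metrics import (
    MetricSet,
    aggregate_over_auts,
    compute_metrics,
    miss_rate_by_type,
    most_missed_per_bin,
    percent,
    relative_difference,
    rule_delta,
)
from .stats import compare_groups

logger = logging.getLogger(__name__)

__all__ = ["evaluate", "compare_rules", "error_analysis"]

DEFAULT_SPACING = (0.7, 0.7)  # mm, midpoint of the typical in-plane range


def _spacing_of(
    case_id: str, case_meta: Mapping[str, CaseRecord] | None
) -> tuple[float, float]:
    if case_meta and case_id in case_meta:
        return case_meta[case_id].pixel_spacing_mm
    return DEFAULT_SPACING


def evaluate(
    references: Mapping[str, Sequence[ReferenceNodule]],
    predictions: Mapping[str, Sequence[PredictedNodule]],
    rule: MatchRule,
    case_meta: Mapping[str, CaseRecord] | None = None,
    order: MatchOrder = MatchOrder.size,
    type_scope: Iterable[NoduleType] | None = None,
) -> tuple[MetricSet, dict[str, MatchResult], list[dict]]:
    """Match one AUT's predictions against the reference standard.

    Returns pooled metrics, per-case match results, and audit rows — one per
    reference nodule (TP/FN with matched pred_id and tiebreak score) and one
    per unmatched prediction (FP). Predictions for a case absent from the
    references are logged and counted as FP within their own case.
    """
    scope = set(type_scope) if type_scope is not None else None
    results: dict[str, MatchResult] = {}
    audit: list[dict] = []
    all_cases = sorted(set(references) | set(predictions))
    for case_id in all_cases:
        refs = list(references.get(case_id, []))
        preds = list(predictions.get(case_id, []))
        if case_id not in references and preds:
            logger.warning(
                "case %s has predictions but no reference annotations; "
                "all %d predictions counted as FP",
                case_id,
                len(preds),
            )
        res = match_case_scoped(
            refs, preds, rule, _spacing_of(case_id, case_meta), order, scope
        )
        results[case_id] = res
        matched = res.matched_pred_of
        scores = {nid: s for nid, _, s in res.assignments}
        for r in refs:
            if scope is not None and r.type not in scope:
                continue
            if r.nodule_id in matched:
                audit.append(
                    {
                        "case_id": case_id,
                        "kind": "reference",
                        "id": r.nodule_id,
                        "outcome": "TP",
                        "matched_id": matched[r.nodule_id],
                        "tiebreak_score": scores[r.nodule_id],
                    }
                )
            else:
                audit.append(
                    {
                        "case_id": case_id,
                        "kind": "reference",
                        "id": r.nodule_id,
                        "outcome": "FN",
                        "matched_id": "",
                        "tiebreak_score": "",
                    }
                )
        tp_preds = set(matched.values())
        for p in preds:
            if p.pred_id in tp_preds:
                outcome = "TP"
            elif p.pred_id in res.fp_ids:
                outcome = "FP"
            else:
                continue  # dropped by type-scope shadow matching
            audit.append(
                {
                    "case_id": case_id,
                    "kind": "prediction",
                    "id": p.pred_id,
                    "outcome": outcome,
                    "matched_id": "",
                    "tiebreak_score": "",
                }
            )
    return compute_metrics(results), results, audit


def compare_rules(
    references: Mapping[str, Sequence[ReferenceNodule]],
    predictions_by_aut: Mapping[str, Mapping[str, Sequence[PredictedNodule]]],
    rules: Sequence[MatchRule],
    case_meta: Mapping[str, CaseRecord] | None = None,
    baseline: RuleKind = RuleKind.center_hit,
    order: MatchOrder = MatchOrder.size,
    type_scope: Iterable[NoduleType] | None = None,
    welch: bool = False,
    paired: bool = False,
) -> dict:
    """Evaluate every AUT under every rule and compare the rules as groups.

    The report carries per-rule mean ± SD of each metric over AUTs (percent
    scale), pairwise rule deltas in percentage points, per-AUT relative TP
    differences against the baseline rule, and ANOVA + pairwise t-tests with
    significance labels per metric.
    """
    if len(rules) < 2:
        raise ValueError("compare_rules needs >= 2 rules")
    auts = sorted(predictions_by_aut)
    if len(auts) < 2:
        raise ValueError("compare_rules needs >= 2 AUTs")

    per_rule: dict[str, dict[str, MetricSet]] = {}
    for rule in rules:
        per_rule[rule.kind.value] = {}
        for aut in auts:
            ms, _, _ = evaluate(
                references,
                predictions_by_aut[aut],
                rule,
                case_meta,
                order,
                type_scope,
            )
            per_rule[rule.kind.value][aut] = ms

    metric_names = ("recall", "precision", "f1")
    summary: dict[str, dict] = {}
    groups_by_metric: dict[str, dict[str, list[float]]] = {m: {} for m in metric_names}
    for rname, by_aut in per_rule.items():
        entry: dict = {"per_aut": {a: m.as_dict() for a, m in by_aut.items()}}
        for metric in metric_names:
            vals = [percent(getattr(by_aut[a], metric)) for a in auts]
            mean, sd = aggregate_over_auts(vals)
            entry[metric] = {"mean": round(mean, 2), "sd": round(sd, 2)}
            groups_by_metric[metric][rname] = vals
        summary[rname] = entry

    deltas: dict[str, dict[str, float]] = {}
    base_name = baseline.value
    if base_name not in per_rule:
        raise ValueError(f"baseline rule {base_name} not among evaluated rules")
    for rname in per_rule:
        if rname == base_name:
            continue
        means_base = {m: summary[base_name][m]["mean"] for m in metric_names}
        means_other = {m: summary[rname][m]["mean"] for m in metric_names}
        deltas[f"{base_name}_minus_{rname}"] = rule_delta(means_base, means_other)

    rd: dict[str, dict[str, float]] = {}
    for rname, by_aut in per_rule.items():
        if rname == base_name:
            continue
        rd[rname] = {}
        for aut in auts:
            tp_base = per_rule[base_name][aut].tp
            if tp_base > 0:
                rd[rname][aut] = round(
                    relative_difference(by_aut[aut].tp, tp_base), 4
                )
            else:
                rd[rname][aut] = None

    stats_report = {
        metric: compare_groups(groups_by_metric[metric], welch=welch, paired=paired).as_dict()
        for metric in metric_names
    }

    return {
        "auts": auts,
        "baseline": base_name,
        "summary": summary,
        "rule_deltas_pp": deltas,
        "relative_difference_vs_baseline": rd,
        "stats": stats_report,
    }


def error_analysis(
    references: Mapping[str, Sequence[ReferenceNodule]],
    predictions_by_aut: Mapping[str, Mapping[str, Sequence[PredictedNodule]]],
    rule: MatchRule | None = None,
    case_meta: Mapping[str, CaseRecord] | None = None,
    order: MatchOrder = MatchOrder.size,
    type_scope: Iterable[NoduleType] | None = None,
) -> dict:
    """Stratified FN analysis under one rule (center hit by default).

    Produces the per-type miss-rate table (per AUT, with mean ± SD) and the
    most-missed heatmap: per size bin, how many AUTs have each type as their
    highest miss rate.
    """
    rule = rule or MatchRule(RuleKind.center_hit)
    results_by_aut: dict[str, dict[str, MatchResult]] = {}
    for aut in sorted(predictions_by_aut):
        _, results, _ = evaluate(
            references, predictions_by_aut[aut], rule, case_meta, order, type_scope
        )
        results_by_aut[aut] = results
    scoped_refs = references
    if type_scope is not None:
        scope = set(type_scope)
        scoped_refs = {
            cid: [r for r in refs if r.type in scope]
            for cid, refs in references.items()
        }
    miss = miss_rate_by_type(results_by_aut, scoped_refs)
    heat, ties = most_missed_per_bin(results_by_aut, scoped_refs)
    return {
        "rule": rule.kind.value,
        "miss_rate_by_type": {
            t.value: {
                k: (round(v, 4) if isinstance(v, float) else v)
                for k, v in row.items()
            }
            for t, row in miss.items()
        },
        "most_missed_heatmap": {
            b.value: {t.value: c for t, c in row.items()} for b, row in heat.items()
        },
        "heatmap_ties": [(aut, b.value) for aut, b in ties],
    }
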