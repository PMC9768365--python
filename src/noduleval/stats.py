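"""Group comparison of mark-labeling rules: ANOVA, pairwise t-tests, star labels.

Each rule yields one metric value per AUT; rules are compared as groups with
a one-way fixed-effects ANOVA followed by uncorrected pairwise two-sample
t-tests (Student's pooled-variance by default; Welch available). Per-AUT
values are treated as independent observations across groups, mirroring the
common reporting style, although they are in fact paired by AUT — a paired
test is available via ``paired=True``.

Significance labels: ``**`` for p <= 0.01, ``*`` for 0.01 < p <= 0.05,
``ns`` for p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "one_way_anova",
    "two_sample_t",
    "significance_label",
    "compare_groups",
    "GroupComparison",
]


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA over k >= 2 groups.

    Returns (F, p) with p from the F distribution on (k-1, N-k) degrees of
    freedom. Identical groups with zero between-group variance give F = 0,
    p = 1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs >= 2 values")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    if np.isnan(f):  # all values identical everywhere: no variance at all
        return 0.0, 1.0
    return float(f), float(p)


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
    paired: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    Default is Student's pooled-variance test; ``welch=True`` drops the
    equal-variance assumption, ``paired=True`` runs a paired test instead
    (a and b must then align element-wise by AUT). Degenerate zero-variance
    input with equal means returns (0, 1).
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length samples")
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if not np.isfinite(t):
        # zero pooled variance: nan when the means agree too, +/-inf otherwise
        if np.isnan(t) and np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise FloatingPointError(
            "zero variance with unequal means: t statistic degenerate"
        )
    return float(t), float(p)


def significance_label(p: float) -> str:
    """Map a p-value to the conventional star label (boundaries inclusive)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """ANOVA plus all pairwise tests over named groups of per-AUT values."""

    groups: dict[str, list[float]]
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], tuple[float, float]]

    @property
    def labels(self) -> dict[tuple[str, str], str]:
        return {k: significance_label(p) for k, (_, p) in self.pairwise.items()}

    def as_dict(self) -> dict:
        return {
            "anova": {"F": self.anova_F, "p": self.anova_p,
                      "label": significance_label(self.anova_p)},
            "pairs": [
                {"a": a, "b": b, "t": t, "p": p, "label": significance_label(p)}
                for (a, b), (t, p) in self.pairwise.items()
            ],
        }


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    welch: bool = False,
    paired: bool = False,
) -> GroupComparison:
    """Run the full comparison: one ANOVA plus every pairwise t-test."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups to compare")
    F, p = one_way_anova(*[groups[n] for n in names])
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairwise[(a, b)] = two_sample_t(
                groups[a], groups[b], welch=welch, paired=paired
            )
    return GroupComparison(
        groups={n: list(map(float, groups[n])) for n in names},
        anova_F=F,
        anova_p=p,
        pairwise=pairwise,
    )
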