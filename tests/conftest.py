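"""Shared builders for matching/metrics tests.

Fixtures construct tiny in-memory cases; nothing is read from disk except
through tempfile round-trips inside individual tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from noduleval.data_model import (
    Box2D,
    NoduleType,
    PredictedNodule,
    ReferenceNodule,
    SliceAnnotation,
)

UNIT = (1.0, 1.0)


def make_ref(
    nodule_id: str,
    boxes: list[tuple[int, float, float, float, float]],
    long_d: float = 8.0,
    short_d: float = 6.0,
    ntype: NoduleType = NoduleType.solid,
    case_id: str = "case01",
    avg_d: float | None = None,
) -> ReferenceNodule:
    slices = [
        SliceAnnotation(Box2D(*b), long_diameter_mm=long_d, short_diameter_mm=short_d)
        for b in boxes
    ]
    return ReferenceNodule(
        case_id=case_id,
        nodule_id=nodule_id,
        type=ntype,
        slices=slices,
        average_diameter_mm=avg_d if avg_d is not None else (long_d + short_d) / 2,
    )


def make_pred(
    pred_id: str,
    boxes: list[tuple[int, float, float, float, float]],
    case_id: str = "case01",
) -> PredictedNodule:
    return PredictedNodule(case_id, pred_id, [Box2D(*b) for b in boxes])


def random_case(rng: np.random.Generator, n_refs: int, n_preds: int, case_id="case01"):
    """A small random case on a 100x100 grid with 1-3 slice stacks.

    Boxes overlap freely so every match topology (0, 1 or many candidates
    per reference, shared candidates across references) gets exercised.
    """
    refs, preds = [], []
    for i in range(n_refs):
        z0 = int(rng.integers(0, 4))
        nz = int(rng.integers(1, 4))
        x = float(rng.uniform(5, 80))
        y = float(rng.uniform(5, 80))
        w = float(rng.uniform(4, 18))
        h = float(rng.uniform(4, 18))
        boxes = [(z0 + k, x, y, x + w, y + h) for k in range(nz)]
        long_d = float(rng.uniform(3, 14))
        short_d = float(rng.uniform(1, long_d))
        refs.append(make_ref(f"n{i}", boxes, long_d, short_d, case_id=case_id))
    for j in range(n_preds):
        z0 = int(rng.integers(0, 5))
        nz = int(rng.integers(1, 4))
        x = float(rng.uniform(0, 85))
        y = float(rng.uniform(0, 85))
        w = float(rng.uniform(3, 20))
        h = float(rng.uniform(3, 20))
        boxes = [(z0 + k, x, y, x + w, y + h) for k in range(nz)]
        preds.append(make_pred(f"p{j}", boxes, case_id=case_id))
    return refs, preds


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
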