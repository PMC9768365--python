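"""Canonical domain types and CSV schemas for nodule detection evaluation.

The evaluation framework scores algorithm-under-test (AUT) outputs against an
expert reference standard. Both sides are stacks of per-slice axis-aligned
bounding boxes: a reference nodule additionally carries a type label and
long/short diameters per slice, an AUT prediction optionally carries a score.

Coordinate convention: boxes are half-open pixel rectangles
``[x_min, x_max) x [y_min, y_max)`` on a 0-based slice index; the box center
is ``((x_min+x_max)/2, (y_min+y_max)/2)``. Diameters are stored in mm as
annotated; conversion between pixels and mm uses per-case pixel spacing.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Box2D",
    "SliceAnnotation",
    "NoduleType",
    "ReferenceNodule",
    "PredictedNodule",
    "CaseRecord",
    "SizeBin",
    "size_bin_of",
    "read_reference_csv",
    "read_prediction_csv",
    "read_case_metadata_csv",
    "write_reference_csv",
    "write_prediction_csv",
    "SchemaError",
    "VocabularyError",
    "ValidationError",
]

REFERENCE_COLUMNS = [
    "case_id",
    "nodule_id",
    "type",
    "slice_index",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
    "long_diameter_mm",
    "short_diameter_mm",
    "avg_diameter_mm",
]

PREDICTION_COLUMNS = [
    "case_id",
    "pred_id",
    "slice_index",
    "x_min",
    "y_min",
    "x_max",
    "y_max",
]

CASE_METADATA_COLUMNS = [
    "case_id",
    "pixel_spacing_row_mm",
    "pixel_spacing_col_mm",
    "slice_thickness_mm",
]


class SchemaError(ValueError):
    """A CSV is missing a required column or has a malformed header."""


class VocabularyError(ValueError):
    """A categorical field holds a value outside its fixed vocabulary."""


class ValidationError(ValueError):
    """A row violates a domain invariant (degenerate box, duplicate key...)."""


class NoduleType(str, enum.Enum):
    """The six-way reference taxonomy of pulmonary nodules."""

    solid = "solid"
    part_solid = "part_solid"
    pure_ground_glass = "pure_ground_glass"
    calcified = "calcified"
    pleural = "pleural"
    pleural_calcified = "pleural_calcified"

    def __str__(self) -> str:  # stable serialization
        return self.value


class SizeBin(str, enum.Enum):
    """Average-diameter bins, left-closed / right-open so they partition (0, inf)."""

    lt4 = "[0,4)"
    d4_6 = "[4,6)"
    d6_10 = "[6,10)"
    ge10 = "[10,inf)"

    def __str__(self) -> str:
        return self.value


_SIZE_BIN_EDGES = [(4.0, SizeBin.lt4), (6.0, SizeBin.d4_6), (10.0, SizeBin.d6_10)]


def size_bin_of(average_diameter_mm: float) -> SizeBin:
    """Map a positive average diameter (mm) to its size bin.

    Bins are ``[0,4), [4,6), [6,10), [10,inf)``: a diameter of exactly 4.0 mm
    falls in ``[4,6)`` and 10.0 mm in ``[10,inf)``.
    """
    if not average_diameter_mm > 0:
        raise ValueError(f"diameter must be > 0, got {average_diameter_mm}")
    for upper, b in _SIZE_BIN_EDGES:
        if average_diameter_mm < upper:
            return b
    return SizeBin.ge10


@dataclass(frozen=True)
class Box2D:
    """Axis-aligned half-open bounding box on one CT slice."""

    slice_index: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.slice_index < 0:
            raise ValidationError(f"slice_index must be >= 0, got {self.slice_index}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Closed-region containment: the boundary counts as inside."""
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class SliceAnnotation:
    """One reference slice: box, diameters (mm) and an optional boundary polygon."""

    box: Box2D
    long_diameter_mm: float
    short_diameter_mm: float
    boundary: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.long_diameter_mm > 0 or not self.short_diameter_mm > 0:
            raise ValidationError("diameters must be > 0")
        if self.short_diameter_mm > self.long_diameter_mm:
            raise ValidationError("short diameter exceeds long diameter")
        if self.boundary is not None and len(self.boundary) < 3:
            raise ValidationError("boundary polygon needs >= 3 vertices")


@dataclass
class ReferenceNodule:
    """A multi-slice annotated ground-truth nodule."""

    case_id: str
    nodule_id: str
    type: NoduleType
    slices: list[SliceAnnotation]
    average_diameter_mm: float

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError(f"nodule {self.nodule_id}: needs >= 1 slice")
        idx = [s.box.slice_index for s in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"nodule {self.nodule_id}: slice indices not strictly increasing"
            )
        if not self.average_diameter_mm > 0:
            raise ValidationError(f"nodule {self.nodule_id}: average diameter must be > 0")

    @property
    def largest_slice(self) -> SliceAnnotation:
        """The slice with maximal box area; ties resolved to the lowest slice index."""
        return max(self.slices, key=lambda s: (s.box.area, -s.box.slice_index))

    @property
    def matching_radius_mm(self) -> float:
        """Adaptive center-distance threshold: max over slices of (long+short)/4 mm."""
        return max((s.long_diameter_mm + s.short_diameter_mm) / 4.0 for s in self.slices)

    @property
    def size_bin(self) -> SizeBin:
        return size_bin_of(self.average_diameter_mm)

    def slice_map(self) -> dict[int, SliceAnnotation]:
        return {s.box.slice_index: s for s in self.slices}


@dataclass
class PredictedNodule:
    """An AUT-output bounding-box stack for one predicted nodule."""

    case_id: str
    pred_id: str
    boxes: list[Box2D]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.boxes:
            raise ValidationError(f"prediction {self.pred_id}: needs >= 1 box")
        idx = [b.slice_index for b in self.boxes]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"prediction {self.pred_id}: slice indices not strictly increasing"
            )

    def box_map(self) -> dict[int, Box2D]:
        return {b.slice_index: b for b in self.boxes}


@dataclass
class CaseRecord:
    """One CT case: acquisition geometry, reference nodules, per-AUT predictions."""

    case_id: str
    pixel_spacing_mm: tuple[float, float]  # (row, col) i.e. (y, x)
    slice_thickness_mm: float
    references: list[ReferenceNodule] = field(default_factory=list)
    predictions_by_aut: dict[str, list[PredictedNodule]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.pixel_spacing_mm:
            if not (0 < sp < 5):
                raise ValidationError(
                    f"case {self.case_id}: pixel spacing {sp} outside (0, 5) mm"
                )
        if not self.slice_thickness_mm > 0:
            raise ValidationError(f"case {self.case_id}: slice thickness must be > 0")
        for n in self.references:
            if n.case_id != self.case_id:
                raise ValidationError("reference nodule case_id mismatch")
        for preds in self.predictions_by_aut.values():
            for p in preds:
                if p.case_id != self.case_id:
                    raise ValidationError("prediction case_id mismatch")


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

def _load_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, cols: Iterable[str], path: str | Path) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & (df[c] != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValidationError(f"{path}: non-numeric value in column {c!r} at line {row}")
        df[c] = parsed
    return df


def _check_unique(df: pd.DataFrame, keys: list[str], path: str | Path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        lines = [str(i + 2) for i in df.index[dup]]
        raise ValidationError(
            f"{path}: duplicate {tuple(keys)} rows at lines {', '.join(lines)}"
        )


def read_reference_csv(path: str | Path) -> dict[str, list[ReferenceNodule]]:
    """Read a reference-standard CSV into nodules grouped by case.

    Schema (exact header): ``case_id,nodule_id,type,slice_index,x_min,y_min,
    x_max,y_max,long_diameter_mm,short_diameter_mm,avg_diameter_mm``.
    One row per nodule per slice; rows sharing (case_id, nodule_id) form one
    multi-slice nodule. Duplicate (case_id, nodule_id, slice_index) rows are
    rejected.
    """
    df = _load_csv(path, REFERENCE_COLUMNS)
    num_cols = REFERENCE_COLUMNS[3:]
    df = _numeric(df, num_cols, path)
    _check_unique(df, ["case_id", "nodule_id", "slice_index"], path)

    valid_types = {t.value for t in NoduleType}
    bad_types = set(df["type"]) - valid_types
    if bad_types:
        raise VocabularyError(
            f"{path}: unknown nodule type(s) {sorted(bad_types)}; "
            f"expected one of {sorted(valid_types)}"
        )

    out: dict[str, list[ReferenceNodule]] = {}
    for (case_id, nodule_id), grp in df.groupby(["case_id", "nodule_id"], sort=True):
        grp = grp.sort_values("slice_index")
        try:
            slices = [
                SliceAnnotation(
                    box=Box2D(int(r.slice_index), r.x_min, r.y_min, r.x_max, r.y_max),
                    long_diameter_mm=r.long_diameter_mm,
                    short_diameter_mm=r.short_diameter_mm,
                )
                for r in grp.itertuples()
            ]
        except ValidationError as e:
            raise ValidationError(f"{path}: nodule ({case_id},{nodule_id}): {e}") from e
        nod = ReferenceNodule(
            case_id=str(case_id),
            nodule_id=str(nodule_id),
            type=NoduleType(grp["type"].iloc[0]),
            slices=slices,
            average_diameter_mm=float(grp["avg_diameter_mm"].iloc[0]),
        )
        out.setdefault(str(case_id), []).append(nod)
    return out


def read_prediction_csv(path: str | Path) -> dict[str, list[PredictedNodule]]:
    """Read an AUT prediction CSV into predictions grouped by case.

    Schema: ``case_id,pred_id,slice_index,x_min,y_min,x_max,y_max[,score]``.
    An empty data section is valid (an AUT may output nothing). Output order
    is deterministic: case_id then pred_id lexicographic, slices ascending.
    """
    df = _load_csv(path, PREDICTION_COLUMNS)
    num_cols = PREDICTION_COLUMNS[2:] + (["score"] if "score" in df.columns else [])
    df = _numeric(df, num_cols, path)
    if df.empty:
        return {}
    _check_unique(df, ["case_id", "pred_id", "slice_index"], path)

    out: dict[str, list[PredictedNodule]] = {}
    for (case_id, pred_id), grp in df.groupby(["case_id", "pred_id"], sort=True):
        grp = grp.sort_values("slice_index")
        boxes = [
            Box2D(int(r.slice_index), r.x_min, r.y_min, r.x_max, r.y_max)
            for r in grp.itertuples()
        ]
        score = None
        if "score" in grp.columns:
            s = grp["score"].iloc[0]
            score = float(s) if s == s and s != "" else None
        out.setdefault(str(case_id), []).append(
            PredictedNodule(str(case_id), str(pred_id), boxes, score)
        )
    return out


def read_case_metadata_csv(path: str | Path) -> dict[str, CaseRecord]:
    """Read per-case geometry: pixel spacing (row, col) and slice thickness."""
    df = _load_csv(path, CASE_METADATA_COLUMNS)
    df = _numeric(df, CASE_METADATA_COLUMNS[1:], path)
    _check_unique(df, ["case_id"], path)
    return {
        str(r.case_id): CaseRecord(
            case_id=str(r.case_id),
            pixel_spacing_mm=(r.pixel_spacing_row_mm, r.pixel_spacing_col_mm),
            slice_thickness_mm=r.slice_thickness_mm,
        )
        for r in df.itertuples()
    }


def write_reference_csv(
    nodules_by_case: Mapping[str, Sequence[ReferenceNodule]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    rows = []
    for case_id in sorted(nodules_by_case):
        for n in nodules_by_case[case_id]:
            for s in n.slices:
                rows.append(
                    (
                        n.case_id,
                        n.nodule_id,
                        n.type.value,
                        s.box.slice_index,
                        s.box.x_min,
                        s.box.y_min,
                        s.box.x_max,
                        s.box.y_max,
                        s.long_diameter_mm,
                        s.short_diameter_mm,
                        n.average_diameter_mm,
                    )
                )
    _write_rows(path, REFERENCE_COLUMNS, rows, header_comment)


def write_prediction_csv(
    preds_by_case: Mapping[str, Sequence[PredictedNodule]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    rows = []
    any_score = any(
        p.score is not None for ps in preds_by_case.values() for p in ps
    )
    cols = PREDICTION_COLUMNS + (["score"] if any_score else [])
    for case_id in sorted(preds_by_case):
        for p in sorted(preds_by_case[case_id], key=lambda q: q.pred_id):
            for b in p.boxes:
                row = [p.case_id, p.pred_id, b.slice_index, b.x_min, b.y_min, b.x_max, b.y_max]
                if any_score:
                    row.append("" if p.score is None else p.score)
                rows.append(tuple(row))
    _write_rows(path, cols, rows, header_comment)


def _write_rows(path, columns, rows, header_comment):
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(",".join(columns) + "\n")
        for row in rows:
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    # repr of a float is the shortest exact decimal, so write/read round-trips
    if isinstance(v, float):
        return repr(v)
    return str(v)


def count_rows(nodules_by_case: Mapping[str, Sequence[ReferenceNodule]]) -> Counter:
    """Slice-row counts per case; used for grouping-conservation checks."""
    return Counter(
        {c: sum(len(n.slices) for n in ns) for c, ns in nodules_by_case.items()}
    )
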