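"""Synthetic test-set and AUT-output simulation.

No patient data ships with the package; this module generates a multi-case
reference standard that mimics the composition of a real sequestered lung-CT
test set — the six-type mixture (solid 42.66%, part-solid 5.06%, pure
ground-glass 19.58%, calcified 7.40%, pleural 23.06%, pleural calcified
2.24%), the size-bin mixture over average diameter (69.91% below 4 mm,
19.63% in [4,6), 7.28% in [6,10), 3.18% at 10 mm or above, truncated at
30 mm as the nodule definitions require), a mean of about 10.3 nodules per
case, and multi-slice extents with an elliptic in-plane taper toward the end
slices.

Simulated AUTs detect each reference nodule independently with a
configurable per-(type, size-bin) sensitivity; detected nodules are copied
with Gaussian center jitter, a log-normal box-size error and optional
truncation of boundary slices, and Poisson-count false positives are placed
away from every reference nodule so the configured sensitivities stay
identifiable from the evaluation output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import (
    Box2D,
    CaseRecord,
    NoduleType,
    PredictedNodule,
    ReferenceNodule,
    SizeBin,
    SliceAnnotation,
    size_bin_of,
    write_prediction_csv,
    write_reference_csv,
)

__all__ = [
    "DatasetSpec",
    "AUTProfile",
    "GenerationError",
    "generate_reference_dataset",
    "simulate_aut",
    "DEFAULT_TYPE_PROPORTIONS",
    "DEFAULT_SIZE_BIN_PROPORTIONS",
]

DEFAULT_TYPE_PROPORTIONS: dict[NoduleType, float] = {
    NoduleType.solid: 0.4266,
    NoduleType.part_solid: 0.0506,
    NoduleType.pure_ground_glass: 0.1958,
    NoduleType.calcified: 0.0740,
    NoduleType.pleural: 0.2306,
    NoduleType.pleural_calcified: 0.0224,
}

DEFAULT_SIZE_BIN_PROPORTIONS: dict[SizeBin, float] = {
    SizeBin.lt4: 0.6991,
    SizeBin.d4_6: 0.1963,
    SizeBin.d6_10: 0.0728,
    SizeBin.ge10: 0.0318,
}

# Panel study conditions: per-type detection probability of the simulated
# AUTs, mirroring the detection rates implied by published per-type miss
# rates of real CAD panels (pure ground-glass hardest, calcified easiest);
# the pleural-calcified value is interpolated since no rate is printed for it.
PANEL_SENSITIVITY: dict[NoduleType, float] = {
    NoduleType.pure_ground_glass: 0.41,
    NoduleType.pleural: 0.50,
    NoduleType.solid: 0.58,
    NoduleType.pleural_calcified: 0.65,
    NoduleType.part_solid: 0.71,
    NoduleType.calcified: 0.73,
}

# diameter support per bin (mm); log-uniform within; [10, inf) truncated at 30
_BIN_RANGES: dict[SizeBin, tuple[float, float]] = {
    SizeBin.lt4: (1.0, 4.0),
    SizeBin.d4_6: (4.0, 6.0),
    SizeBin.d6_10: (6.0, 10.0),
    SizeBin.ge10: (10.0, 30.0),
}

# in-plane axis ratio: long = ECC * avg, short = (2 - ECC) * avg, so the
# average of the two diameters recovers the sampled value exactly
_ECC = 1.1
_MIN_TAPER = 0.35


class GenerationError(RuntimeError):
    """Nodule placement failed; try fewer or smaller nodules."""


@dataclass
class DatasetSpec:
    """Parameters of a synthetic reference dataset."""

    n_cases: int = 50
    nodules_per_case_mean: float = 10.3  # Poisson mean, ~6109 nodules / 593 cases
    type_proportions: Mapping[NoduleType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    size_bin_proportions: Mapping[SizeBin, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_BIN_PROPORTIONS)
    )
    pixel_spacing_range_mm: tuple[float, float] = (0.5, 0.9)
    slice_thickness_range_mm: tuple[float, float] = (1.0, 2.0)
    image_extent_px: int = 512
    n_slices: int = 320
    seed: int = 0

    def __post_init__(self) -> None:
        for name, props in (
            ("type_proportions", self.type_proportions),
            ("size_bin_proportions", self.size_bin_proportions),
        ):
            total = sum(props.values())
            if any(w < 0 for w in props.values()):
                raise ValueError(f"{name}: negative weight")
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: weights sum to {total}, expected 1")
        if self.n_cases <= 0:
            raise ValueError("n_cases must be > 0")

    def to_json(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "nodules_per_case_mean": self.nodules_per_case_mean,
            "type_proportions": {t.value: w for t, w in self.type_proportions.items()},
            "size_bin_proportions": {
                b.value: w for b, w in self.size_bin_proportions.items()
            },
            "pixel_spacing_range_mm": list(self.pixel_spacing_range_mm),
            "slice_thickness_range_mm": list(self.slice_thickness_range_mm),
            "image_extent_px": self.image_extent_px,
            "n_slices": self.n_slices,
            "seed": self.seed,
        }


@dataclass
class AUTProfile:
    """Error structure of one simulated algorithm under test.

    ``sensitivity`` may be a scalar, a per-type mapping, or a mapping keyed
    by (type, size-bin); the most specific entry wins.
    """

    sensitivity: float | Mapping = 0.6
    center_jitter_sigma: float = 0.1  # fraction of nodule radius, per axis
    box_scale_sigma: float = 0.1  # sd of log box-size multiplier
    fp_per_case_mean: float = 2.0
    slice_truncation_prob: float = 0.0
    seed: int = 0
    label: str = "AUT"

    def __post_init__(self) -> None:
        if self.center_jitter_sigma < 0 or self.box_scale_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.fp_per_case_mean < 0:
            raise ValueError("fp_per_case_mean must be >= 0")
        if not (0 <= self.slice_truncation_prob <= 1):
            raise ValueError("slice_truncation_prob must be in [0, 1]")

    def sensitivity_of(self, t: NoduleType, b: SizeBin) -> float:
        s = self.sensitivity
        if isinstance(s, Mapping):
            for key in ((t, b), t, t.value):
                if key in s:
                    s = s[key]
                    break
            else:
                raise KeyError(f"no sensitivity entry for {t}")
        s = float(s)
        if not (0 <= s <= 1):
            raise ValueError(f"sensitivity {s} outside [0, 1]")
        return s


def _sample_diameter(rng: np.random.Generator, b: SizeBin) -> float:
    lo, hi = _BIN_RANGES[b]
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _taper(u: float) -> float:
    """Elliptic in-plane shrink factor at normalized slice offset u in [-1, 1]."""
    return max(_MIN_TAPER, math.sqrt(max(0.0, 1.0 - u * u)))


def _build_nodule(
    rng: np.random.Generator,
    case_id: str,
    nodule_id: str,
    ntype: NoduleType,
    avg_d: float,
    center_xy: tuple[float, float],
    spacing: tuple[float, float],
    slice_thickness: float,
    n_slices: int,
) -> ReferenceNodule:
    long_d = _ECC * avg_d
    short_d = (2.0 - _ECC) * avg_d
    n_z = max(1, round(avg_d / slice_thickness))
    n_z = min(n_z, n_slices)
    z0 = int(rng.integers(0, n_slices - n_z + 1))
    cx, cy = center_xy
    # normalize so the largest slice carries exactly the annotated diameters
    factors = [
        _taper(0.0 if n_z == 1 else (2.0 * k - (n_z - 1)) / n_z) for k in range(n_z)
    ]
    peak = max(factors)
    slices = []
    for k in range(n_z):
        f = factors[k] / peak
        half_w = f * long_d / 2.0 / spacing[1]  # x extent from long axis
        half_h = f * short_d / 2.0 / spacing[0]
        slices.append(
            SliceAnnotation(
                box=Box2D(z0 + k, cx - half_w, cy - half_h, cx + half_w, cy + half_h),
                long_diameter_mm=f * long_d,
                short_diameter_mm=f * short_d,
            )
        )
    return ReferenceNodule(
        case_id=case_id,
        nodule_id=nodule_id,
        type=ntype,
        slices=slices,
        average_diameter_mm=avg_d,
    )


def generate_reference_dataset(spec: DatasetSpec) -> dict[str, CaseRecord]:
    """Generate a reproducible multi-case reference standard.

    For each case, the nodule count is Poisson, each nodule draws a type and
    a size bin from the configured mixtures with a log-uniform diameter
    within the bin, and in-plane placement is rejection-sampled so nodule
    neighborhoods do not overlap (100 tries, then the diameter is halved; a
    further failure raises :class:`GenerationError`).
    """
    rng = np.random.default_rng(spec.seed)
    types = list(spec.type_proportions)
    type_w = np.array([spec.type_proportions[t] for t in types], dtype=float)
    bins = list(spec.size_bin_proportions)
    bin_w = np.array([spec.size_bin_proportions[b] for b in bins], dtype=float)

    width = len(str(spec.n_cases))
    cases: dict[str, CaseRecord] = {}
    for ci in range(spec.n_cases):
        case_id = f"case{ci:0{width}d}"
        spacing = (
            float(rng.uniform(*spec.pixel_spacing_range_mm)),
            float(rng.uniform(*spec.pixel_spacing_range_mm)),
        )
        thickness = float(rng.uniform(*spec.slice_thickness_range_mm))
        n_nod = int(rng.poisson(spec.nodules_per_case_mean))
        placed: list[tuple[float, float, float]] = []  # (cx, cy, radius_px)
        refs: list[ReferenceNodule] = []
        for ni in range(n_nod):
            ntype = types[int(rng.choice(len(types), p=type_w))]
            b = bins[int(rng.choice(len(bins), p=bin_w))]
            avg_d = _sample_diameter(rng, b)
            center = None
            d = avg_d
            for attempt in range(201):
                if attempt == 100:  # shrink once, as a packing fallback
                    d = max(_BIN_RANGES[SizeBin.lt4][0], d / 2.0)
                r_px = _ECC * d / 2.0 / min(spacing)
                margin = r_px + 2.0
                if 2 * margin >= spec.image_extent_px:
                    continue
                cx = float(rng.uniform(margin, spec.image_extent_px - margin))
                cy = float(rng.uniform(margin, spec.image_extent_px - margin))
                if all(
                    math.hypot(cx - px, cy - py) > r_px + pr + 2.0
                    for px, py, pr in placed
                ):
                    center = (cx, cy)
                    avg_d = d
                    break
            if center is None:
                raise GenerationError(
                    f"{case_id}: could not place nodule {ni}; "
                    "reduce nodules_per_case_mean or nodule sizes"
                )
            placed.append((center[0], center[1], _ECC * avg_d / 2.0 / min(spacing)))
            refs.append(
                _build_nodule(
                    rng,
                    case_id,
                    f"n{ni:03d}",
                    ntype,
                    avg_d,
                    center,
                    spacing,
                    thickness,
                    spec.n_slices,
                )
            )
        cases[case_id] = CaseRecord(
            case_id=case_id,
            pixel_spacing_mm=spacing,
            slice_thickness_mm=thickness,
            references=refs,
        )
    return cases


def simulate_aut(
    cases: Mapping[str, CaseRecord], profile: AUTProfile
) -> dict[str, list[PredictedNodule]]:
    """Simulate one AUT's predictions over a generated dataset.

    Each reference nodule is detected independently with its configured
    sensitivity; a detection copies the reference box stack with a shared
    Gaussian center offset (sd = jitter fraction x nodule radius, per axis,
    in pixels), a log-normal size multiplier, and boundary slices dropped
    with ``slice_truncation_prob`` per end. False positives per case are
    Poisson-distributed and placed with their centers outside every
    reference box dilated by the nodule radius.
    """
    rng = np.random.default_rng(profile.seed)
    out: dict[str, list[PredictedNodule]] = {}
    for case_id in sorted(cases):
        case = cases[case_id]
        spacing = case.pixel_spacing_mm
        preds: list[PredictedNodule] = []
        k = 0
        for ref in case.references:
            s = profile.sensitivity_of(ref.type, size_bin_of(ref.average_diameter_mm))
            if rng.random() >= s:
                continue
            r_px = ref.average_diameter_mm / 2.0 / min(spacing)
            dx = rng.normal(0.0, profile.center_jitter_sigma * r_px)
            dy = rng.normal(0.0, profile.center_jitter_sigma * r_px)
            scale = math.exp(rng.normal(0.0, profile.box_scale_sigma))
            boxes = []
            for sl in ref.slices:
                b = sl.box
                cx = (b.x_min + b.x_max) / 2.0 + dx
                cy = (b.y_min + b.y_max) / 2.0 + dy
                hw = (b.x_max - b.x_min) / 2.0 * scale
                hh = (b.y_max - b.y_min) / 2.0 * scale
                boxes.append(Box2D(b.slice_index, cx - hw, cy - hh, cx + hw, cy + hh))
            if profile.slice_truncation_prob > 0:
                if len(boxes) > 1 and rng.random() < profile.slice_truncation_prob:
                    boxes = boxes[1:]
                if len(boxes) > 1 and rng.random() < profile.slice_truncation_prob:
                    boxes = boxes[:-1]
            preds.append(PredictedNodule(case_id, f"p{k:03d}", boxes))
            k += 1
        for _ in range(int(rng.poisson(profile.fp_per_case_mean))):
            fp = _place_false_positive(rng, case, k)
            if fp is not None:
                preds.append(fp)
                k += 1
        out[case_id] = preds
    return out


def _place_false_positive(
    rng: np.random.Generator, case: CaseRecord, k: int
) -> PredictedNodule | None:
    spacing = case.pixel_spacing_mm
    extent = 512.0
    d = float(math.exp(rng.uniform(math.log(2.0), math.log(8.0))))
    half = d / 2.0 / min(spacing)
    keepout = []
    for ref in case.references:
        r_px = ref.average_diameter_mm / 2.0 / min(spacing)
        for sl in ref.slices:
            b = sl.box
            keepout.append(
                (b.x_min - r_px, b.y_min - r_px, b.x_max + r_px, b.y_max + r_px)
            )
    for _ in range(200):
        cx = float(rng.uniform(half + 1, extent - half - 1))
        cy = float(rng.uniform(half + 1, extent - half - 1))
        if all(not (x0 <= cx <= x1 and y0 <= cy <= y1) for x0, y0, x1, y1 in keepout):
            z = int(rng.integers(0, 300))
            return PredictedNodule(
                case.case_id,
                f"p{k:03d}",
                [Box2D(z, cx - half, cy - half, cx + half, cy + half)],
            )
    return None


def default_panel(
    n_auts: int = 10,
    seed: int = 0,
    center_jitter_sigma: float = 0.15,
    box_scale_sigma: float = 0.25,
    fp_per_case_mean: float = 8.0,
    slice_truncation_prob: float = 0.05,
) -> list[AUTProfile]:
    """The canonical simulated ten-AUT panel.

    Every profile shares the per-type sensitivities of
    :data:`PANEL_SENSITIVITY` and the stated error structure; the AUTs
    differ by their random seed, so the spread across them is sampling
    noise, as in a panel of algorithms tuned to similar operating points.
    """
    return [
        AUTProfile(
            sensitivity=dict(PANEL_SENSITIVITY),
            center_jitter_sigma=center_jitter_sigma,
            box_scale_sigma=box_scale_sigma,
            fp_per_case_mean=fp_per_case_mean,
            slice_truncation_prob=slice_truncation_prob,
            seed=seed * 1009 + 17 * (i + 1),
            label=f"aut{i + 1:02d}",
        )
        for i in range(n_auts)
    ]


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_dataset(
    cases: Mapping[str, CaseRecord],
    out_dir: str | Path,
    spec: DatasetSpec,
) -> None:
    """Emit reference CSV, case-metadata CSV and a spec.json sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refs = {cid: c.references for cid, c in cases.items()}
    write_reference_csv(refs, out_dir / "reference.csv", header_comment=f"seed={spec.seed}")
    with (out_dir / "cases.csv").open("w", encoding="utf-8") as fh:
        fh.write(f"# seed={spec.seed}\n")
        fh.write("case_id,pixel_spacing_row_mm,pixel_spacing_col_mm,slice_thickness_mm\n")
        for cid in sorted(cases):
            c = cases[cid]
            fh.write(
                f"{cid},{c.pixel_spacing_mm[0]!r},{c.pixel_spacing_mm[1]!r},"
                f"{c.slice_thickness_mm!r}\n"
            )
    (out_dir / "spec.json").write_text(json.dumps(spec.to_json(), indent=2))


def write_aut_predictions(
    preds: Mapping[str, list[PredictedNodule]],
    out_dir: str | Path,
    profile: AUTProfile,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{profile.label}.csv"
    write_prediction_csv(preds, path, header_comment=f"seed={profile.seed}")
    return path
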