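"""FROC evaluation: matching, threshold sweeps, size stratification.

The hit criterion is *center-in-box*: a detection hits an annotated nodule
when the nodule's center falls inside the detection box. Hits are assigned
optimally (maximum number of hits, ties resolved toward larger total
detection score), each truth is credited at most once, and surplus
detections landing on an already-hit nodule are not penalized as false
positives — only detections containing no nodule center are.

A FROC curve sweeps a descending score-threshold ladder; each threshold
yields one (sensitivity, mean false positives per image) operating point.
The summary area integrates sensitivity over FP/image on [0, fp_cap] and is
normalized by fp_cap so a perfect detector scores 1.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import Detection, DetectionSet
from .ensemble import threshold_detections
from .lung_roi import RoiBox

__all__ = [
    "GroundTruthNodule",
    "SizeStratum",
    "DEFAULT_STRATA",
    "FrocPoint",
    "FrocCurve",
    "THRESHOLD_LADDER",
    "match_detections",
    "froc",
    "sensitivity_by_size",
    "summarize_sizes",
    "read_ground_truth",
    "write_ground_truth",
]

#: The standard descending score-threshold ladder used for FROC sweeps.
THRESHOLD_LADDER = (0.1, 0.075, 0.05, 0.02, 0.01, 0.0075, 0.005, 0.0025, 0.001, 0.0001)


@dataclass(frozen=True)
class GroundTruthNodule:
    """An annotated nodule: center, physical diameter, and pixel box."""

    image_id: str
    center_x: float
    center_y: float
    diameter_mm: float
    box: RoiBox

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")
        if not self.box.contains_point(self.center_x, self.center_y):
            raise ValueError(
                f"nodule center ({self.center_x}, {self.center_y}) outside its box"
            )


@dataclass(frozen=True)
class SizeStratum:
    """Half-open diameter stratum [lower_mm, upper_mm) in millimetres."""

    label: str
    lower_mm: float
    upper_mm: float

    def contains(self, diameter_mm: float) -> bool:
        return self.lower_mm <= diameter_mm < self.upper_mm


#: The five clinical size strata; boundaries are half-open so 10 mm
#: belongs to "10–20 mm".
DEFAULT_STRATA = (
    SizeStratum("<6 mm", 0.0, 6.0),
    SizeStratum("6–10 mm", 6.0, 10.0),
    SizeStratum("10–20 mm", 10.0, 20.0),
    SizeStratum("20–30 mm", 20.0, 30.0),
    SizeStratum(">30 mm", 30.0, float("inf")),
)


@dataclass(frozen=True)
class FrocPoint:
    threshold: float
    sensitivity: float
    fp_per_image: float


@dataclass(frozen=True)
class FrocCurve:
    """Operating points ordered by descending threshold, plus summary area."""

    points: tuple[FrocPoint, ...]
    n_images: int
    n_nodules: int
    area: float
    fp_cap: float

    def __post_init__(self) -> None:
        sens = [p.sensitivity for p in self.points]
        fps = [p.fp_per_image for p in self.points]
        if any(b < a - 1e-12 for a, b in zip(sens, sens[1:])):
            raise ValueError("sensitivity must be non-increasing in threshold")
        if any(b < a - 1e-12 for a, b in zip(fps, fps[1:])):
            raise ValueError("fp_per_image must be non-increasing in threshold")


def match_detections(
    dets: DetectionSet, truths: Sequence[GroundTruthNodule]
) -> tuple[dict[int, Detection | None], list[Detection]]:
    """Assign detections to annotated nodules under the center-in-box criterion.

    Returns ``(hits, fps)`` where ``hits`` maps each truth index to its
    matched detection (or None) and ``fps`` lists the false positives.
    The assignment maximizes the number of hit nodules, then the total
    matched score. A detection whose box contains the center of some
    nodule — matched or surplus — is never a false positive.
    """
    for t in truths:
        if t.image_id != dets.image_id:
            raise ValueError(
                f"image_id mismatch: detections {dets.image_id!r} vs truth {t.image_id!r}"
            )
    n_d, n_t = len(dets.detections), len(truths)
    hits: dict[int, Detection | None] = {i: None for i in range(n_t)}
    if n_d == 0 or n_t == 0:
        return hits, list(dets.detections)

    feasible = np.zeros((n_d, n_t), dtype=bool)
    for i, d in enumerate(dets.detections):
        for j, t in enumerate(truths):
            feasible[i, j] = d.box.contains_point(t.center_x, t.center_y)

    # weight = 1 + eps*score for feasible pairs: hit count dominates,
    # score breaks ties among equal-cardinality assignments
    eps = 1.0 / (2.0 * max(n_d, n_t) + 2.0)
    weights = np.where(
        feasible,
        1.0 + eps * np.array([d.score for d in dets.detections])[:, None],
        0.0,
    )
    rows, cols = linear_sum_assignment(weights, maximize=True)
    matched_dets = set()
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            hits[j] = dets.detections[i]
            matched_dets.add(i)

    fps = [
        d
        for i, d in enumerate(dets.detections)
        if i not in matched_dets and not feasible[i].any()
    ]
    return hits, fps


def _evaluate_at_threshold(
    sets: Mapping[str, DetectionSet],
    truths_by_image: Mapping[str, list[GroundTruthNodule]],
    threshold: float,
) -> tuple[dict[tuple[str, int], bool], int]:
    """Per-truth hit flags and total FP count at one threshold."""
    hit_flags: dict[tuple[str, int], bool] = {}
    n_fp = 0
    for image_id, ds in sets.items():
        truths = truths_by_image.get(image_id, [])
        thr = threshold_detections(ds, threshold)
        hits, fps = match_detections(thr, truths)
        for j in range(len(truths)):
            hit_flags[(image_id, j)] = hits[j] is not None
        n_fp += len(fps)
    return hit_flags, n_fp


def _index_inputs(
    sets: Iterable[DetectionSet], truths: Sequence[GroundTruthNodule]
) -> tuple[dict[str, DetectionSet], dict[str, list[GroundTruthNodule]]]:
    by_image: dict[str, DetectionSet] = {}
    for ds in sets:
        if ds.image_id in by_image:
            raise ValueError(f"duplicate detection set for image {ds.image_id!r}")
        by_image[ds.image_id] = ds
    truths_by_image: dict[str, list[GroundTruthNodule]] = {}
    for t in truths:
        truths_by_image.setdefault(t.image_id, []).append(t)
    missing = set(truths_by_image) - set(by_image)
    if missing:
        raise ValueError(f"truth images without detection sets: {sorted(missing)[:5]}")
    return by_image, truths_by_image


def froc(
    sets: Iterable[DetectionSet],
    truths: Sequence[GroundTruthNodule],
    thresholds: Sequence[float] = THRESHOLD_LADDER,
    fp_cap: float = 10.0,
) -> FrocCurve:
    """Sweep the threshold ladder into a FROC curve with normalized area.

    Sensitivity = hit nodules / all nodules, FP/image = total false
    positives / number of images, both over the full image set at each
    threshold. The area is the trapezoidal integral of sensitivity over
    FP/image on [0, fp_cap] (curve extended horizontally past its last
    point, anchored at FP = 0), divided by fp_cap.
    """
    if not truths:
        raise ValueError("sensitivity undefined: empty ground-truth list")
    by_image, truths_by_image = _index_inputs(sets, truths)
    n_images = len(by_image)
    n_nodules = len(truths)

    pts = []
    for t in sorted(thresholds, reverse=True):
        hit_flags, n_fp = _evaluate_at_threshold(by_image, truths_by_image, t)
        pts.append(
            FrocPoint(
                threshold=t,
                sensitivity=sum(hit_flags.values()) / n_nodules,
                fp_per_image=n_fp / n_images,
            )
        )

    area = _froc_area(pts, fp_cap)
    return FrocCurve(
        points=tuple(pts), n_images=n_images, n_nodules=n_nodules, area=area, fp_cap=fp_cap
    )


def _froc_area(pts: Sequence[FrocPoint], fp_cap: float) -> float:
    """Normalized trapezoidal area under (fp_per_image, sensitivity)."""
    xs = [p.fp_per_image for p in pts]
    ys = [p.sensitivity for p in pts]
    # ascending FP order (points come in descending threshold = ascending FP);
    # anchored at FP = 0 with the highest-threshold sensitivity (horizontal
    # extension, mirroring the rightward extension past the last point)
    if xs[0] > 0:
        xs = [0.0] + xs
        ys = [ys[0]] + ys
    if xs[-1] < fp_cap:
        xs = xs + [fp_cap]
        ys = ys + [ys[-1]]
    xs_a, ys_a = np.asarray(xs), np.asarray(ys)
    keep = xs_a <= fp_cap
    if not keep.all():
        y_cap = float(np.interp(fp_cap, xs_a, ys_a))
        xs_a = np.append(xs_a[keep], fp_cap)
        ys_a = np.append(ys_a[keep], y_cap)
    return float(np.trapezoid(ys_a, xs_a)) / fp_cap


def sensitivity_by_size(
    sets: Iterable[DetectionSet],
    truths: Sequence[GroundTruthNodule],
    threshold: float,
    strata: Sequence[SizeStratum] = DEFAULT_STRATA,
) -> dict[str, tuple[int, float | None]]:
    """Per-stratum (n, sensitivity) at one operating threshold.

    Empty strata report ``(0, None)``.
    """
    by_image, truths_by_image = _index_inputs(sets, truths)
    hit_flags, _ = _evaluate_at_threshold(by_image, truths_by_image, threshold)

    out: dict[str, tuple[int, float | None]] = {}
    for s in strata:
        idx = [
            (t.image_id, j)
            for image_id, ts in truths_by_image.items()
            for j, t in enumerate(ts)
            if s.contains(t.diameter_mm)
        ]
        n = len(idx)
        out[s.label] = (n, (sum(hit_flags[k] for k in idx) / n) if n else None)
    return out


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_sizes(
    truths: Sequence[GroundTruthNodule],
    total: int,
    strata: Sequence[SizeStratum] = DEFAULT_STRATA,
) -> pd.DataFrame:
    """Cohort size-distribution table: (stratum, count, percent).

    Percentages are 100*count/total rounded half away from zero to one
    decimal, the convention of clinical characteristics tables. Raises if
    the stratum counts do not sum to ``total``.
    """
    counts = {s.label: 0 for s in strata}
    for t in truths:
        for s in strata:
            if s.contains(t.diameter_mm):
                counts[s.label] += 1
                break
    n_sum = sum(counts.values())
    if n_sum != total:
        raise ValueError(f"stratum counts sum to {n_sum}, expected total {total}")
    rows = [
        {"stratum": lbl, "count": c, "percent": _round_half_up(100.0 * c / total, 1)}
        for lbl, c in counts.items()
    ]
    return pd.DataFrame(rows)


_GT_COLUMNS = ["image_id", "center_x", "center_y", "diameter_mm", "x0", "y0", "x1", "y1"]


def read_ground_truth(path: str | os.PathLike) -> list[GroundTruthNodule]:
    """Read nodule annotations from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_GT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns: {sorted(missing)}")
    return [
        GroundTruthNodule(
            image_id=str(r.image_id),
            center_x=float(r.center_x),
            center_y=float(r.center_y),
            diameter_mm=float(r.diameter_mm),
            box=RoiBox(int(r.x0), int(r.y0), int(r.x1), int(r.y1)),
        )
        for r in df.itertuples(index=False)
    ]


def write_ground_truth(truths: Sequence[GroundTruthNodule], path: str | os.PathLike) -> None:
    """Write nodule annotations to CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_GT_COLUMNS)
        for t in truths:
            w.writerow(
                [t.image_id, t.center_x, t.center_y, t.diameter_mm,
                 t.box.x0, t.box.y0, t.box.x1, t.box.y1]
            )


def write_froc(curve: FrocCurve, csv_path: str | os.PathLike) -> None:
    """Write FROC operating points to CSV."""
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "sensitivity", "fp_per_image"])
        for p in curve.points:
            w.writerow([p.threshold, p.sensitivity, p.fp_per_image])
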