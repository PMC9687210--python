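"""Threshold-then-union ensembling of detector outputs.

The ensemble is a fourth "model" built from the three preprocessing-variant
detectors: each member's detections are thresholded at its own operating
point, pooled as a set union, and overlapping boxes (one physical finding
reported by several members) are merged greedily by IoU so a finding is
counted once. The surviving box and score come from the highest-scoring
member detection in each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .detection import Detection, DetectionSet
from .lung_roi import RoiBox

__all__ = ["EnsembleConfig", "threshold_detections", "union_ensemble", "box_iou"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Per-member score thresholds and the IoU at which boxes merge.

    The default 0.01 threshold for each of the three preprocessing variants
    is the operating point at which union ensembling trades best between
    added sensitivity and added false positives.
    """

    member_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"default": 0.01, "gamma": 0.01, "clahe": 0.01}
    )
    merge_iou: float = 0.5

    def __post_init__(self) -> None:
        for tag, t in self.member_thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {tag!r} must be in [0, 1], got {t}")
        if not 0.0 <= self.merge_iou <= 1.0:
            raise ValueError(f"merge_iou must be in [0, 1], got {self.merge_iou}")


def threshold_detections(ds: DetectionSet, t: float) -> DetectionSet:
    """Keep detections with score >= t, preserving order."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    return DetectionSet(
        image_id=ds.image_id,
        detections=tuple(d for d in ds if d.score >= t),
    )


def box_iou(a: RoiBox, b: RoiBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    return inter / (a.area + b.area - inter)


def union_ensemble(
    members: Sequence[DetectionSet], cfg: EnsembleConfig = EnsembleConfig()
) -> DetectionSet:
    """Union the members' above-threshold detections for one image.

    Each member is thresholded at its configured operating point (members
    with no configured threshold default to 0, i.e. all detections kept);
    pooled detections are clustered greedily in descending score order
    (ties broken by box position for determinism), absorbing any detection
    with IoU >= ``merge_iou`` with the cluster seed. Each cluster emits one
    detection carrying the seed's box and the cluster's maximal score under
    the tag ``"ensemble"``.
    """
    if not members:
        raise ValueError("at least one member required")
    ids = {m.image_id for m in members}
    if len(ids) != 1:
        raise ValueError(f"members must share one image_id, got {sorted(ids)}")
    image_id = members[0].image_id

    pooled: list[Detection] = []
    for m in members:
        for d in m:
            t = cfg.member_thresholds.get(d.model_tag, 0.0)
            if d.score >= t:
                pooled.append(d)
    pooled.sort(key=lambda d: (-d.score, d.box.x0, d.box.y0, d.box.x1, d.box.y1))

    out: list[Detection] = []
    remaining = pooled
    while remaining:
        seed, rest = remaining[0], remaining[1:]
        cluster = [seed] + [d for d in rest if box_iou(seed.box, d.box) >= cfg.merge_iou]
        remaining = [d for d in rest if box_iou(seed.box, d.box) < cfg.merge_iou]
        out.append(
            Detection(
                box=seed.box,
                score=max(d.score for d in cluster),
                model_tag="ensemble",
            )
        )
    return DetectionSet(image_id=image_id, detections=tuple(out))
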