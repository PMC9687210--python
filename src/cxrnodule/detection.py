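"""Detection data model, JSONL adapter, and a deterministic toy detector.

Trained detectors (e.g. a YOLO run) live outside this package; their outputs
enter through the JSONL adapter and are evaluated by the same downstream
code as the built-in toy detector. The toy detector is a plain multiscale
difference-of-Gaussian blob finder: deterministic, dependency-light, and
good enough on phantom images to exercise ensembling and FROC machinery.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage

from .images import GrayImage
from .lung_roi import RoiBox, RoiCrop

__all__ = [
    "Detection",
    "DetectionSet",
    "Detector",
    "ToyBlobDetector",
    "map_to_source",
    "read_detections",
    "write_detections",
]

_KNOWN_TAGS = {"default", "gamma", "clahe", "toy", "ensemble"}


@dataclass(frozen=True)
class Detection:
    """One scored candidate box in source-image coordinates."""

    box: RoiBox
    score: float
    model_tag: str = "toy"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.model_tag not in _KNOWN_TAGS and not self.model_tag.startswith("external:"):
            raise ValueError(
                f"model_tag must be one of {sorted(_KNOWN_TAGS)} or 'external:<name>', "
                f"got {self.model_tag!r}"
            )


@dataclass(frozen=True)
class DetectionSet:
    """Ordered detections for one image; may be empty."""

    image_id: str
    detections: tuple[Detection, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "detections", tuple(self.detections))

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)


#: Contract for pluggable detector backends.
Detector = Callable[[GrayImage], DetectionSet]


class ToyBlobDetector:
    """Multiscale difference-of-Gaussian bright-blob detector.

    Adjacent Gaussian scales from ``sigma_ladder`` are differenced and
    approximately scale-normalized (divided by ``ratio - 1``); local maxima
    of the scale-space stack above ``response_floor`` become detections with
    box side ``2 * sqrt(2) * sigma`` of the maximizing scale. Scores are the
    raw responses normalized to [0, 1] by the maximal response over the
    image set processed together (``detect_set``), so one calibration holds
    across a dataset. Deterministic: identical input gives bitwise-identical
    output.
    """

    def __init__(
        self,
        sigma_ladder: Sequence[float] = (3.0, 4.2, 6.0, 8.5, 12.0, 17.0, 24.0),
        response_floor: float = 0.02,
        model_tag: str = "toy",
    ) -> None:
        sig = tuple(float(s) for s in sigma_ladder)
        if len(sig) < 2 or any(s <= 0 for s in sig) or any(
            b <= a for a, b in zip(sig, sig[1:])
        ):
            raise ValueError("sigma_ladder must be >= 2 strictly increasing positive scales")
        self.sigma_ladder = sig
        self.response_floor = float(response_floor)
        self.model_tag = model_tag

    def responses(
        self, img: GrayImage, within: np.ndarray | None = None
    ) -> list[tuple[int, int, float, float]]:
        """Raw blob candidates as (y, x, sigma, response) above the floor.

        ``within``, when given, is a boolean raster restricting candidate
        maxima (e.g. the lung-field mask): blob-like anatomy outside it —
        mediastinal band, body boundary — is then never reported.
        """
        px = img.pixels
        smoothed = [ndimage.gaussian_filter(px, s, mode="nearest") for s in self.sigma_ladder]
        stack = []
        for i in range(len(self.sigma_ladder) - 1):
            ratio = self.sigma_ladder[i + 1] / self.sigma_ladder[i]
            stack.append((smoothed[i] - smoothed[i + 1]) / (ratio - 1.0))
        cube = np.stack(stack)
        local_max = cube == ndimage.maximum_filter(cube, size=(3, 3, 3), mode="nearest")
        cand = local_max & (cube > self.response_floor)
        if within is not None:
            if within.shape != px.shape:
                raise ValueError("within mask shape must match image shape")
            cand &= within[None, :, :]
        out = []
        for k, y, x in zip(*np.nonzero(cand)):
            sigma = float(np.sqrt(self.sigma_ladder[k] * self.sigma_ladder[k + 1]))
            out.append((int(y), int(x), sigma, float(cube[k, y, x])))
        # deterministic order: descending response, then position
        out.sort(key=lambda t: (-t[3], t[0], t[1]))
        return out

    def detect_set(
        self,
        images: Iterable[GrayImage],
        within: Sequence[np.ndarray] | None = None,
    ) -> list[DetectionSet]:
        """Detect over an image set, normalizing scores by the set maximum."""
        images = list(images)
        masks = list(within) if within is not None else [None] * len(images)
        if len(masks) != len(images):
            raise ValueError("one within mask per image required")
        per_image = [(img, self.responses(img, m)) for img, m in zip(images, masks)]
        max_resp = max(
            (r for _, cands in per_image for *_, r in cands), default=0.0
        )
        out = []
        for img, cands in per_image:
            dets = []
            for y, x, sigma, resp in cands:
                half = np.sqrt(2.0) * sigma
                x0, x1 = int(np.floor(x - half)), int(np.ceil(x + half))
                y0, y1 = int(np.floor(y - half)), int(np.ceil(y + half))
                x0, y0 = max(0, x0), max(0, y0)
                x1 = min(img.width, max(x1, x0 + 1))
                y1 = min(img.height, max(y1, y0 + 1))
                score = resp / max_resp if max_resp > 0 else 0.0
                dets.append(
                    Detection(
                        box=RoiBox(x0, y0, x1, y1),
                        score=min(1.0, score),
                        model_tag=self.model_tag,
                    )
                )
            out.append(DetectionSet(image_id=img.id, detections=tuple(dets)))
        return out

    def calibrate_floor(
        self,
        blank_images: Iterable[GrayImage],
        within: Sequence[np.ndarray] | None = None,
        margin: float = 1.05,
    ) -> float:
        """Set the floor just above the strongest response on nodule-free images."""
        images = list(blank_images)
        masks = list(within) if within is not None else [None] * len(images)
        floor_backup = self.response_floor
        self.response_floor = -np.inf
        try:
            peak = max(
                (r for img, m in zip(images, masks) for *_, r in self.responses(img, m)),
                default=0.0,
            )
        finally:
            self.response_floor = floor_backup
        self.response_floor = float(peak) * margin
        return self.response_floor


def map_to_source(ds: DetectionSet, crop: RoiCrop) -> DetectionSet:
    """Translate ROI-local detections back to source-image coordinates."""
    dets = []
    for d in ds:
        b = d.box
        dets.append(
            replace(
                d,
                box=RoiBox(
                    b.x0 + crop.box.x0, b.y0 + crop.box.y0,
                    b.x1 + crop.box.x0, b.y1 + crop.box.y0,
                ),
            )
        )
    return DetectionSet(image_id=ds.image_id, detections=tuple(dets))


_FIELDS = ("x0", "y0", "x1", "y1", "score", "model_tag")


def write_detections(sets: Iterable[DetectionSet], path: str | os.PathLike) -> None:
    """Write detection sets as JSONL, one image per line."""
    with open(path, "w") as fh:
        for ds in sets:
            rec = {
                "image_id": ds.image_id,
                "detections": [
                    {
                        "x0": d.box.x0, "y0": d.box.y0, "x1": d.box.x1, "y1": d.box.y1,
                        "score": d.score, "model_tag": d.model_tag,
                    }
                    for d in ds
                ],
            }
            fh.write(json.dumps(rec) + "\n")


def read_detections(path: str | os.PathLike) -> list[DetectionSet]:
    """Read JSONL detection sets, validating schema and invariants.

    Malformed records raise ``ValueError`` naming the image_id and field.
    Unknown model tags are preserved as ``external:<name>``.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"line {lineno}: invalid JSON: {e}") from e
            image_id = rec.get("image_id")
            if not isinstance(image_id, str):
                raise ValueError(f"line {lineno}: missing or non-string field 'image_id'")
            dets = []
            for d in rec.get("detections", []):
                for f in _FIELDS[:5]:
                    if f not in d:
                        raise ValueError(f"image {image_id!r}: missing field {f!r}")
                score = d["score"]
                if not 0.0 <= score <= 1.0:
                    raise ValueError(
                        f"image {image_id!r}: field 'score' out of range: {score}"
                    )
                tag = d.get("model_tag", "external:unknown")
                if tag not in _KNOWN_TAGS and not tag.startswith("external:"):
                    tag = f"external:{tag}"
                try:
                    box = RoiBox(int(d["x0"]), int(d["y0"]), int(d["x1"]), int(d["y1"]))
                except ValueError as e:
                    raise ValueError(f"image {image_id!r}: field 'box' invalid: {e}") from e
                dets.append(Detection(box=box, score=float(score), model_tag=tag))
            out.append(DetectionSet(image_id=image_id, detections=tuple(dets)))
    return out
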