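"""End-to-end composition: preprocess -> segment -> ROI -> detect -> map back.

Convenience layer used by the CLI, the test suite and downstream analyses;
each step remains individually accessible through its own module.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .detection import DetectionSet, ToyBlobDetector, map_to_source
from .images import GrayImage
from .lung_roi import LungMask, crop_to_roi, fallback_segment, roi_from_mask
from .preprocess import ClaheParams, GammaParams, NormalizationParams, preprocess_variant

__all__ = ["prepare_rois", "detect_variant"]


def prepare_rois(
    images: Iterable[GrayImage],
    variant: str = "default",
    np_: NormalizationParams = NormalizationParams(),
    gp: GammaParams = GammaParams(),
    cp: ClaheParams = ClaheParams(),
):
    """Preprocess each image, segment lungs, and crop to the expanded ROI.

    Returns a list of ``(crop, lung_mask_in_roi)`` pairs. The lung mask is
    taken on the Stage-I (default-variant) image so all three enhancement
    variants share one geometry, then cropped to the ROI.
    """
    out = []
    for img in images:
        base = preprocess_variant(img, "default", np_, gp, cp)
        mask = fallback_segment(base)
        if mask.is_empty:
            raise ValueError(f"segmentation found no lung in {img.id!r}")
        box = roi_from_mask(mask)
        pre = base if variant == "default" else preprocess_variant(img, variant, np_, gp, cp)
        crop = crop_to_roi(pre, box)
        mask_roi = mask.mask[box.y0 : box.y1, box.x0 : box.x1]
        out.append((crop, mask_roi))
    return out


def detect_variant(
    images: Sequence[GrayImage],
    variant: str,
    detector: ToyBlobDetector,
    blank_images: Sequence[GrayImage] | None = None,
    model_tag: str | None = None,
) -> list[DetectionSet]:
    """Run the toy detector on one preprocessing variant of an image set.

    When ``blank_images`` (nodule-free) are given, the response floor is
    first calibrated just above their strongest in-lung response.
    Detections are returned in source-image coordinates under
    ``model_tag`` (default: the variant name).
    """
    detector.model_tag = model_tag or variant
    if blank_images is not None:
        blanks = prepare_rois(blank_images, variant)
        detector.calibrate_floor([c.image for c, _ in blanks], within=[m for _, m in blanks])
    prepared = prepare_rois(images, variant)
    sets = detector.detect_set([c.image for c, _ in prepared], within=[m for _, m in prepared])
    return [map_to_source(ds, crop) for ds, (crop, _) in zip(sets, prepared)]
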