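"""Lung region-of-interest construction.

A detector should see the whole area where a nodule can hide: both lung
fields, the mediastinum between them, the retrocardiac region and the
subdiaphragmatic area that naive lung masks cut off. The ROI is therefore a
single box: the tight bounding box of the (two-lung) mask, padded laterally
and extended inferiorly, then clipped to the image.

Lung segmentation itself is pluggable (any callable GrayImage -> LungMask);
:func:`fallback_segment` is a deterministic intensity-based stand-in adequate
for phantom images, not a clinical segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from skimage import measure, segmentation

from .images import GrayImage

__all__ = [
    "LungMask",
    "RoiBox",
    "Segmenter",
    "fallback_segment",
    "roi_from_mask",
    "crop_to_roi",
    "RoiCrop",
]


@dataclass(frozen=True)
class LungMask:
    """Binary lung-field mask congruent with its source image."""

    mask: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned pixel box, 0-based, half-open: [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box ({self.x0},{self.y0},{self.x1},{self.y1})")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("box coordinates must be non-negative")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


#: Contract for pluggable segmentation backends.
Segmenter = Callable[[GrayImage], LungMask]


def fallback_segment(
    img: GrayImage,
    low_quantile: float = 0.35,
    min_component_area_fraction: float = 0.01,
) -> LungMask:
    """Threshold-based lung-field stand-in segmenter.

    Keeps dark regions (below the ``low_quantile`` intensity quantile),
    drops components touching the image border and components smaller than
    ``min_component_area_fraction`` of the image area, and retains up to the
    two largest remaining components. Expects Stage-I-normalized input
    (air dark). Returns an empty mask when nothing survives; check
    :attr:`LungMask.is_empty`.
    """
    px = img.pixels
    thr = np.quantile(px, low_quantile)
    raw = px < thr
    raw = segmentation.clear_border(raw)
    labels = measure.label(raw, connectivity=2)
    if labels.max() == 0:
        return LungMask(np.zeros_like(raw), source_id=img.id)
    min_area = min_component_area_fraction * px.size
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    props.sort(key=lambda p: p.area, reverse=True)
    keep = {p.label for p in props[:2]}
    mask = np.isin(labels, sorted(keep)) if keep else np.zeros_like(raw)
    return LungMask(mask, source_id=img.id)


def roi_from_mask(
    mask: LungMask,
    lateral_pad_fraction: float = 0.02,
    inferior_extend_fraction: float = 0.15,
) -> RoiBox:
    """Expanded bounding box covering lungs, mediastinum and subdiaphragm.

    The tight box over all foreground pixels already spans the mediastinal
    gap between the lungs. It is padded by ``lateral_pad_fraction`` of the
    box width on each side and extended downward by
    ``inferior_extend_fraction`` of the box height, then clipped to the
    image bounds.
    """
    if mask.is_empty:
        raise ValueError(f"no lung found in mask for {mask.source_id!r}")
    ys, xs = np.nonzero(mask.mask)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    pad = int(round(lateral_pad_fraction * (x1 - x0)))
    ext = int(round(inferior_extend_fraction * (y1 - y0)))
    h, w = mask.mask.shape
    return RoiBox(
        x0=max(0, x0 - pad),
        y0=y0,
        x1=min(w, x1 + pad),
        y1=min(h, y1 + ext),
    )


@dataclass(frozen=True)
class RoiCrop:
    """A cropped sub-image plus the offset needed to map detections back."""

    image: GrayImage
    box: RoiBox

    def to_source_xy(self, x: float, y: float) -> tuple[float, float]:
        """Map ROI-local coordinates back to source-image coordinates."""
        return x + self.box.x0, y + self.box.y0


def crop_to_roi(img: GrayImage, box: RoiBox) -> RoiCrop:
    """Extract the ROI sub-image, recording the crop offset."""
    if box.x1 > img.width or box.y1 > img.height:
        raise ValueError(
            f"box ({box.x0},{box.y0},{box.x1},{box.y1}) outside image "
            f"{img.height}x{img.width}"
        )
    sub = img.pixels[box.y0 : box.y1, box.x0 : box.x1]
    return RoiCrop(image=GrayImage(sub, id=img.id), box=box)
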