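"""Radiograph normalization and contrast-enhancement variants.

Two stages mirror a typical CXR pipeline:

* **Stage I (always applied)** — polarity correction (inverse-grayscale films
  are detected from their border intensity and flipped) followed by brightness
  normalization (the top 0.2 % of intensities is clipped and the histogram
  rescaled to the unit range).
* **Stage II (one of three variants)** — ``default`` (identity), ``gamma``
  (power-law transform ``Vout = A * Vin**gamma`` with ``gamma = 3``), or
  ``clahe`` (contrast-limited adaptive histogram equalization with clip
  limit 2 on an 8x8 tile grid).

The three variants produce three parallel datasets from one input, the
substrate for training/ensembling three parallel detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import GrayImage

__all__ = [
    "NormalizationParams",
    "GammaParams",
    "ClaheParams",
    "VARIANTS",
    "correct_monochrome",
    "correct_brightness",
    "gamma_correct",
    "clahe",
    "preprocess_variant",
]

#: The three enhancement variants, in canonical order.
VARIANTS = ("default", "gamma", "clahe")

#: Tolerance of the quantile interpolation used in brightness rescaling.
QUANTILE_TOL = 1e-6


@dataclass(frozen=True)
class NormalizationParams:
    """Stage-I parameters.

    clip_fraction : top fraction of intensities removed before rescaling
        (0.002 reproduces the "top 0.2 %" convention).
    edge_strip_fraction : width of the four border strips used for the
        polarity check, as a fraction of each image dimension.
    """

    clip_fraction: float = 0.002
    edge_strip_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_fraction <= 0.05:
            raise ValueError(f"clip_fraction must be in (0, 0.05], got {self.clip_fraction}")
        if not 0.0 < self.edge_strip_fraction <= 0.25:
            raise ValueError(
                f"edge_strip_fraction must be in (0, 0.25], got {self.edge_strip_fraction}"
            )


@dataclass(frozen=True)
class GammaParams:
    """Power-law transform parameters: ``Vout = A * Vin**gamma``."""

    A: float = 1.0
    gamma: float = 3.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameters.

    clip_limit : histogram clip as a multiple of the uniform per-tile bin
        level (the common "clipLimit" convention). ``None`` or ``inf``
        disables clipping.
    grid_rows, grid_cols : tile grid dimensions.
    n_bins : histogram resolution; 256 matches 8-bit clinical display.
    """

    clip_limit: float = 2.0
    grid_rows: int = 8
    grid_cols: int = 8
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError(f"clip_limit must be positive, got {self.clip_limit}")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _edge_strip_mean(px: np.ndarray, frac: float) -> float:
    h, w = px.shape
    sh = max(1, int(round(frac * h)))
    sw = max(1, int(round(frac * w)))
    strip = np.zeros_like(px, dtype=bool)
    strip[:sh, :] = True
    strip[-sh:, :] = True
    strip[:, :sw] = True
    strip[:, -sw:] = True
    return float(px[strip].mean())


def correct_monochrome(img: GrayImage, p: NormalizationParams = NormalizationParams()) -> GrayImage:
    """Flip inverse-grayscale images so that air renders dark.

    The mean intensity of the four border strips (each ``edge_strip_fraction``
    of the corresponding dimension wide) is compared against the global
    median: a bright border on a radiograph means reversed polarity, so the
    image is inverted (``v -> 1 - v``). Constant images are never inverted.
    Idempotent: once the border is dark the test cannot fire again.
    """
    px = img.pixels
    if px.max() == px.min():
        return img
    edge_mean = _edge_strip_mean(px, p.edge_strip_fraction)
    if edge_mean > float(np.median(px)):
        return img.with_pixels(1.0 - px)
    return img


def correct_brightness(img: GrayImage, p: NormalizationParams = NormalizationParams()) -> GrayImage:
    """Clip the brightest ``clip_fraction`` of intensities and rescale to [0, 1].

    ``hi`` is the ``1 - clip_fraction`` quantile (linear interpolation of
    order statistics) and ``lo`` the observed minimum; pixels are clipped to
    ``[lo, hi]`` and affinely mapped onto [0, 1]. A constant image maps to
    constant 0.
    """
    px = img.pixels
    hi = float(np.quantile(px, 1.0 - p.clip_fraction))
    lo = float(px.min())
    if hi <= lo:
        return img.with_pixels(np.zeros_like(px))
    out = (np.clip(px, lo, hi) - lo) / (hi - lo)
    return img.with_pixels(out)


def gamma_correct(img: GrayImage, p: GammaParams = GammaParams()) -> GrayImage:
    """Apply the power law ``v -> A * v**gamma``, clipped to [0, 1]."""
    out = np.clip(p.A * np.power(img.pixels, p.gamma), 0.0, 1.0)
    return img.with_pixels(out)


def clahe(img: GrayImage, p: ClaheParams = ClaheParams()) -> GrayImage:
    """Contrast-limited adaptive histogram equalization (Zuiderveld).

    The image is divided into a ``grid_rows x grid_cols`` tile grid; each
    tile's histogram is clipped at ``clip_limit`` times the uniform bin level
    with the excess redistributed uniformly, and equalized through its
    cumulative distribution. Per-pixel output bilinearly interpolates the
    tile mappings between tile centers, which suppresses tile-boundary
    artifacts. With a 1x1 grid and unbounded clip this reduces to global
    histogram equalization.
    """
    px = img.pixels
    h, w = px.shape
    rows, cols = p.grid_rows, p.grid_cols
    if rows > h or cols > w:
        raise ValueError(f"grid {rows}x{cols} larger than image {h}x{w}")
    nb = p.n_bins

    # pad to a multiple of the tile size (edge replication), as is standard
    th = -(-h // rows)
    tw = -(-w // cols)
    ph, pw = th * rows, tw * cols
    padded = np.pad(px, ((0, ph - h), (0, pw - w)), mode="edge")

    bins = np.minimum((padded * nb).astype(np.int64), nb - 1)
    tiles = bins.reshape(rows, th, cols, tw).transpose(0, 2, 1, 3).reshape(rows, cols, th * tw)
    npx = th * tw

    hist = np.zeros((rows, cols, nb), dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            hist[r, c] = np.bincount(tiles[r, c], minlength=nb)

    if p.clip_limit is not None and np.isfinite(p.clip_limit):
        limit = p.clip_limit * npx / nb
        excess = np.clip(hist - limit, 0.0, None).sum(axis=2, keepdims=True)
        hist = np.minimum(hist, limit) + excess / nb

    cdf = np.cumsum(hist, axis=2) / npx  # mapping: bin -> equalized intensity

    # bilinear interpolation of tile mappings between tile centers
    centers_r = (np.arange(rows) + 0.5) * th - 0.5
    centers_c = (np.arange(cols) + 0.5) * tw - 0.5
    yy = np.arange(ph, dtype=np.float64)
    xx = np.arange(pw, dtype=np.float64)

    def _coords(v: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i1 = np.searchsorted(centers, v)  # first center >= v
        i0 = np.clip(i1 - 1, 0, len(centers) - 1)
        i1 = np.clip(i1, 0, len(centers) - 1)
        denom = centers[i1] - centers[i0]
        t = np.where(denom > 0, (v - centers[i0]) / np.where(denom > 0, denom, 1.0), 0.0)
        return i0, i1, np.clip(t, 0.0, 1.0)

    r0, r1, ty = _coords(yy, centers_r)
    c0, c1, tx = _coords(xx, centers_c)

    b = bins
    R0, R1 = r0[:, None], r1[:, None]
    C0, C1 = c0[None, :], c1[None, :]
    TY, TX = ty[:, None], tx[None, :]
    out = (
        (1 - TY) * (1 - TX) * cdf[R0, C0, b]
        + (1 - TY) * TX * cdf[R0, C1, b]
        + TY * (1 - TX) * cdf[R1, C0, b]
        + TY * TX * cdf[R1, C1, b]
    )
    return img.with_pixels(np.clip(out[:h, :w], 0.0, 1.0))


def preprocess_variant(
    img: GrayImage,
    variant: str,
    np_: NormalizationParams = NormalizationParams(),
    gp: GammaParams = GammaParams(),
    cp: ClaheParams = ClaheParams(),
) -> GrayImage:
    """Stage I (polarity + brightness) followed by the chosen Stage-II variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    out = correct_brightness(correct_monochrome(img, np_), np_)
    if variant == "gamma":
        out = gamma_correct(out, gp)
    elif variant == "clahe":
        out = clahe(out, cp)
    return out
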