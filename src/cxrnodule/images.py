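"""Grayscale image container and PNG/TIFF I/O.

All pipeline stages operate on :class:`GrayImage`: a 2-D float raster with
intensities in [0, 1]. Integer images read from disk are converted by
division by ``2**bits - 1``; on write the inverse mapping is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "read_image", "write_image"]

_MIN_SIDE = 8


@dataclass(frozen=True)
class GrayImage:
    """A normalized 2-D intensity raster.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with all values finite and in [0, 1].
    id : str
        Opaque identifier, usually the source file stem. Preserved through
        every preprocessing step so outputs can be traced to inputs.
    """

    pixels: np.ndarray
    id: str = field(default="")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"image {self.id!r}: expected 2-D array, got ndim={px.ndim}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"image {self.id!r}: minimum size is {_MIN_SIDE}x{_MIN_SIDE}, got {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValueError(f"image {self.id!r}: non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"image {self.id!r}: intensities outside [0, 1] "
                f"(range [{px.min():.4g}, {px.max():.4g}])"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a copy carrying new pixel data under the same id."""
        return GrayImage(pixels=pixels, id=self.id)


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a single-channel 8- or 16-bit PNG or TIFF into a GrayImage."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"{path}: unsupported channel count {arr.shape[2]}")
        if arr.shape[2] >= 3 and not (
            np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2])
        ):
            raise ValueError(f"{path}: expected a single-channel grayscale image")
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        px = arr / 255.0
    elif arr.dtype == np.uint16:
        px = arr / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        px = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}")
    stem = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return GrayImage(pixels=px, id=stem)


def write_image(img: GrayImage, path: str | os.PathLike, bits: int = 8) -> None:
    """Write a GrayImage as an 8- or 16-bit PNG/TIFF (by extension)."""
    import imageio.v3 as iio

    if bits == 8:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
    elif bits == 16:
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"bits must be 8 or 16, got {bits}")
    iio.imwrite(path, arr)
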