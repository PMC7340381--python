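"""Raster image container and TIFF I/O.

The unit of analysis everywhere in this package is a 2-D non-negative
intensity grid (raw photon counts or floats) with a known physical pixel
pitch in nanometres.  Pixel size is carried explicitly rather than read
from TIFF tags: microscope acquisition software rarely writes it reliably,
so it is supplied by the caller (or a CLI flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import InvalidArgumentError

__all__ = ["RasterImage", "read_tiff", "write_tiff"]


@dataclass(frozen=True)
class RasterImage:
    """A 2-D intensity image with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.  Integer photon
        counts are promoted to float64 on entry; all internal arithmetic
        is double precision.
    pixel_size
        Physical pixel pitch in nm; must be positive.
    """

    pixels: np.ndarray
    pixel_size: float
    # frozen dataclass: validation + promotion happen once, here
    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InvalidArgumentError(f"expected a 2-D image, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise InvalidArgumentError(f"image must be at least 2x2, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise InvalidArgumentError("image contains non-finite values")
        if np.any(px < 0):
            raise InvalidArgumentError("image contains negative intensities")
        if not (self.pixel_size > 0):
            raise InvalidArgumentError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_size", float(self.pixel_size))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def total_flux(self) -> float:
        return float(self.pixels.sum())

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        """Same geometry, new intensity data."""
        return RasterImage(pixels=pixels, pixel_size=self.pixel_size)


def read_tiff(path, pixel_size: float) -> RasterImage:
    """Load a 2-D grayscale TIFF (8/16-bit unsigned or 32-bit float)."""
    data = tifffile.imread(path)
    data = np.squeeze(np.asarray(data))
    if data.ndim != 2:
        raise InvalidArgumentError(
            f"{path}: expected a single 2-D grayscale plane, got shape {data.shape}"
        )
    return RasterImage(pixels=data, pixel_size=pixel_size)


def write_tiff(path, image: RasterImage, dtype: str = "float32") -> None:
    """Write a raster image as a single-plane grayscale TIFF.

    ``dtype`` may be ``uint8``, ``uint16`` or ``float32``; integer output
    clips to the dtype range and rounds.
    """
    dt = np.dtype(dtype)
    px = image.pixels
    if dt.kind == "u":
        info = np.iinfo(dt)
        px = np.clip(np.rint(px), info.min, info.max)
    tifffile.imwrite(path, px.astype(dt))
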