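r"""Isotropic undecimated (starlet) wavelet transform via the à trous algorithm.

The starlet decomposition of an image :math:`I` is the sequence

.. math::

    a_0 = I, \qquad a_j = h^{\uparrow j-1} * a_{j-1}, \qquad
    d_j = a_{j-1} - a_j,

where :math:`h` is the separable 2-D kernel built from the 1-D B3-spline
taps ``(1, 4, 6, 4, 1)/16`` and :math:`h^{\uparrow j-1}` is the same kernel
dilated "à trous": :math:`2^{j-1}-1` zeros are inserted between adjacent
taps at level :math:`j`.  Every plane keeps the full image resolution
(undecimated), and the transform is trivially inverted by summation:
:math:`I = a_J + \sum_{j=1}^{J} d_j`.

Detail plane :math:`d_j` is a band-pass view of the image at physical
scale :math:`S_j = \delta_P \cdot 2^{j-1}` for pixel pitch
:math:`\delta_P`: level 1 responds to structure about one pixel across,
each further level to structure twice as coarse.

Boundaries are handled by symmetric (edge-repeated mirror) extension, the
standard choice for the starlet, which preserves the constant-annihilation
property of the detail planes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError
from .image import RasterImage

__all__ = [
    "B3_SPLINE_TAPS",
    "ScalingKernel",
    "StarletDecomposition",
    "atrous_dilate",
    "smooth",
    "starlet_decompose",
    "starlet_reconstruct",
    "scale_of_level",
    "max_depth",
]

#: 1-D B3-spline scaling taps; symmetric, sum exactly 1 in binary floats.
B3_SPLINE_TAPS = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class ScalingKernel:
    """B3-spline taps dilated for level ``level`` of the à trous scheme."""

    level: int
    dilated_taps: np.ndarray

    @property
    def base_taps(self) -> np.ndarray:
        return B3_SPLINE_TAPS.copy()

    def kernel_2d(self) -> np.ndarray:
        """Dense separable 2-D kernel (outer product of the 1-D taps)."""
        return np.outer(self.dilated_taps, self.dilated_taps)


@dataclass(frozen=True)
class StarletDecomposition:
    """Approximation ``a_J`` plus detail planes ``d_1 ... d_J``.

    All planes share the shape of the input image; ``pixel_size`` is
    carried over so physical scales can be attached downstream.
    """

    approximation: np.ndarray
    details: tuple[np.ndarray, ...]
    pixel_size: float

    @property
    def depth(self) -> int:
        return len(self.details)

    @property
    def shape(self) -> tuple[int, int]:
        return self.approximation.shape

    def scales(self) -> np.ndarray:
        """Physical scale of each detail plane, in nm, finest first."""
        return np.array(
            [scale_of_level(j, self.pixel_size) for j in range(1, self.depth + 1)]
        )


def atrous_dilate(level: int) -> ScalingKernel:
    """Dilate the B3-spline taps for the given decomposition level.

    At level ``j`` the à trous algorithm inserts ``2**(j-1) - 1`` zeros
    between adjacent taps, giving ``4 * 2**(j-1) + 1`` taps in total; the
    tap sum stays exactly 1.
    """
    if not isinstance(level, (int, np.integer)) or level < 1:
        raise InvalidArgumentError(f"level must be a positive integer, got {level!r}")
    step = 2 ** (level - 1)
    taps = np.zeros(4 * step + 1)
    taps[::step] = B3_SPLINE_TAPS
    return ScalingKernel(level=int(level), dilated_taps=taps)


def max_depth(shape: tuple[int, int]) -> int:
    """Maximum legal decomposition depth: floor(log2(min dimension))."""
    return int(np.floor(np.log2(min(shape))))


def smooth(image: RasterImage | np.ndarray, level: int) -> np.ndarray:
    """One smoothing step ``a_{j-1} -> a_j`` of the à trous scheme.

    Separable convolution with the level-``level`` dilated kernel, rows
    then columns, symmetric boundary extension; output shape equals the
    input shape.  Accepts either a :class:`RasterImage` or a bare array
    (interior planes of the recursion are plain arrays and may be
    negative, so they cannot be RasterImages).
    """
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image, float)
    if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
        raise InvalidArgumentError(f"smooth needs an image of at least 2x2, got {px.shape}")
    taps = atrous_dilate(level).dilated_taps
    out = ndimage.convolve1d(px, taps, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, taps, axis=1, mode="reflect")
    return out


def starlet_decompose(image: RasterImage, depth: int) -> StarletDecomposition:
    """Decompose an image into ``depth`` detail planes plus approximation."""
    limit = max_depth(image.shape)
    if not isinstance(depth, (int, np.integer)) or depth < 1 or depth > limit:
        raise InvalidArgumentError(
            f"depth must be between 1 and {limit} (floor(log2(min(shape)))) "
            f"for a {image.height}x{image.width} image, got {depth!r}"
        )
    a = image.pixels
    details = []
    for j in range(1, int(depth) + 1):
        a_next = smooth(a, j)
        details.append(a - a_next)
        a = a_next
    return StarletDecomposition(
        approximation=a, details=tuple(details), pixel_size=image.pixel_size
    )


def starlet_reconstruct(decomposition: StarletDecomposition) -> RasterImage:
    """Invert the transform by summation: ``a_J + sum(d_j)``.

    Tiny negative values from floating-point cancellation are clipped so
    the result is a valid raster image.
    """
    shape = decomposition.approximation.shape
    for d in decomposition.details:
        if d.shape != shape:
            raise InvalidArgumentError(
                f"plane shape mismatch: {d.shape} vs approximation {shape}"
            )
    total = decomposition.approximation + sum(decomposition.details)
    return RasterImage(
        pixels=np.clip(total, 0.0, None), pixel_size=decomposition.pixel_size
    )


def scale_of_level(level: int, pixel_size: float) -> float:
    """Physical scale of detail level ``j``: ``pixel_size * 2**(j-1)`` nm.

    Level 1 probes single-pixel structure; each subsequent level doubles
    the scale.
    """
    if not isinstance(level, (int, np.integer)) or level < 1:
        raise InvalidArgumentError(f"level must be a positive integer, got {level!r}")
    if not (pixel_size > 0):
        raise InvalidArgumentError(f"pixel_size must be > 0, got {pixel_size}")
    return float(pixel_size) * 2.0 ** (int(level) - 1)
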