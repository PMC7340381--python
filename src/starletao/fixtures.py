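"""Deterministic synthetic specimens.

Fluorophore-density maps with structure at several spatial scales, so the
multi-scale metric and the correction loop are testable without any real
acquisition: curvilinear filaments (actin-like), sub-resolution beads,
and clustered nucleus-like blobs, each over a uniform background.
Identical specs produce bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

from .errors import InvalidArgumentError
from .image import RasterImage

__all__ = ["SpecimenSpec", "make_specimen"]

KINDS = ("filaments", "beads", "blobs")


@dataclass(frozen=True)
class SpecimenSpec:
    """Recipe for one synthetic specimen image.

    ``count`` is the number of filaments / beads / blob clusters;
    ``intensity`` the peak structure brightness and ``background`` the
    uniform floor, both in (expected) photon counts per pixel.
    """

    kind: str = "filaments"
    shape: tuple[int, int] = (400, 400)
    pixel_size: float = 50.0
    count: int = 12
    intensity: float = 1000.0
    background: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidArgumentError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.count < 0:
            raise InvalidArgumentError("count must be >= 0")
        if self.intensity < 0 or self.background < 0:
            raise InvalidArgumentError("intensity and background must be >= 0")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))


def make_specimen(spec: SpecimenSpec) -> RasterImage:
    """Render the specimen described by ``spec`` (reproducible from its seed).

    A zero ``count`` yields a valid background-only image; the metric will
    reject it as degenerate (no detail), which downstream code treats as
    "nothing to measure".
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.zeros(spec.shape)
    if spec.count > 0:
        if spec.kind == "filaments":
            canvas = _filaments(spec, rng)
        elif spec.kind == "beads":
            canvas = _beads(spec, rng)
        else:
            canvas = _blobs(spec, rng)
    return RasterImage(pixels=canvas + spec.background, pixel_size=spec.pixel_size)


def _filaments(spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    """Anti-aliased random-walk curves, 1–3 px wide after smoothing."""
    h, w = spec.shape
    canvas = np.zeros((h, w))
    n_steps = max(h, w)
    for _ in range(spec.count):
        y, x = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        angle = rng.uniform(0, 2 * np.pi)
        brightness = rng.uniform(0.4, 1.0)
        for _ in range(n_steps):
            angle += rng.normal(scale=0.15)  # gentle curvature
            y2 = y + 2.0 * np.sin(angle)
            x2 = x + 2.0 * np.cos(angle)
            if not (0 <= round(y2) <= h - 2 and 0 <= round(x2) <= w - 2):
                break
            rr, cc, val = line_aa(int(round(y)), int(round(x)),
                                  int(round(y2)), int(round(x2)))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc, val = rr[keep], cc[keep], val[keep]
            np.maximum.at(canvas, (rr, cc), brightness * val)
            y, x = y2, x2
    # widen strokes to 1–3 px without erasing the fine scale
    canvas = ndimage.gaussian_filter(canvas, sigma=0.7)
    peak = canvas.max()
    return canvas * (spec.intensity / peak) if peak > 0 else canvas


def _beads(spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    """Sub-resolution point emitters on integer pixels (may coincide)."""
    h, w = spec.shape
    canvas = np.zeros((h, w))
    ys = rng.integers(2, h - 2, size=spec.count)
    xs = rng.integers(2, w - 2, size=spec.count)
    np.add.at(canvas, (ys, xs), spec.intensity)
    return canvas


def _blobs(spec: SpecimenSpec, rng: np.random.Generator) -> np.ndarray:
    """Clusters of Gaussian spots, loosely nucleus-like."""
    h, w = spec.shape
    canvas = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.count):
        cy, cx = rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w)
        n_spots = rng.integers(3, 9)
        for _ in range(n_spots):
            sy = cy + rng.normal(scale=0.04 * h)
            sx = cx + rng.normal(scale=0.04 * w)
            sigma = rng.uniform(1.5, 5.0)
            amp = spec.intensity * rng.uniform(0.3, 1.0)
            canvas += amp * np.exp(
                -((yy - sy) ** 2 + (xx - sx) ** 2) / (2.0 * sigma**2)
            )
    peak = canvas.max()
    return canvas * (spec.intensity / peak) if peak > 0 else canvas
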