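r"""Scalar-Fourier-optics simulator of an incoherent fluorescence microscope.

The imaging model: a circular pupil of numerical aperture NA carries a
phase aberration :math:`\phi = \sum_i c_i Z_i` expressed on the Noll-indexed,
unit-rms Zernike basis.  The amplitude PSF is the Fourier transform of the
pupil function :math:`P \, e^{i\phi}`; the incoherent intensity PSF is its
squared magnitude, normalized to unit sum.  Images are formed by convolving
a fluorophore density map with the intensity PSF, optionally followed by
Poisson photon sampling.

The PSF field is evaluated with a zoomed (matrix) discrete Fourier
transform directly on the requested image pixel grid, so the PSF pitch is
exact for any pixel size — no FFT-grid resampling is involved.

Coefficients are phase rms in radians throughout; ``rad_to_nm`` /
``nm_to_rad`` convert at an explicit wavelength (a deformable mirror is
calibrated in nm of wavefront, and the relevant wavelength differs between
imaging and depletion beams).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import InvalidArgumentError, UndersampledError
from .image import RasterImage

__all__ = [
    "OpticalConfig",
    "ZernikeAberration",
    "PointSpreadFunction",
    "noll_to_nm",
    "zernike_noll",
    "airy_radius",
    "psf_incoherent",
    "strehl_ratio",
    "random_unit_aberration",
    "image_forward",
    "simulated_image_source",
    "rad_to_nm",
    "nm_to_rad",
    "DEFAULT_CORRECTION_MODES",
    "DEPLETION_WAVELENGTH_NM",
]

#: Noll indices corrected by default: astigmatism through spherical.
DEFAULT_CORRECTION_MODES = (5, 6, 7, 8, 9, 10, 11)

#: Depletion-beam wavelength used to state bias amplitudes in nm.
DEPLETION_WAVELENGTH_NM = 775.0


def rad_to_nm(radians: float, wavelength: float = DEPLETION_WAVELENGTH_NM) -> float:
    """Phase rms in radians -> wavefront rms in nm at the given wavelength."""
    return radians * wavelength / (2.0 * math.pi)


def nm_to_rad(nanometers: float, wavelength: float = DEPLETION_WAVELENGTH_NM) -> float:
    """Wavefront rms in nm -> phase rms in radians at the given wavelength."""
    return nanometers * 2.0 * math.pi / wavelength


# ---------------------------------------------------------------------------
# Zernike polynomials, Noll indexing and normalization
# ---------------------------------------------------------------------------

def noll_to_nm(noll_index: int) -> tuple[int, int]:
    """Map a Noll single index ``j >= 1`` to radial/azimuthal orders (n, m).

    Negative ``m`` denotes the sine term, non-negative the cosine term;
    within a radial order, even Noll indices take the cosine term.
    """
    j = int(noll_index)
    if j < 1:
        raise InvalidArgumentError(f"Noll index must be >= 1, got {noll_index}")
    n = int((-1.0 + math.sqrt(8.0 * (j - 1) + 1.0)) / 2.0)
    p = j - n * (n + 1) // 2
    k = n % 2
    m = ((p + k) // 2) * 2 - k
    if m != 0 and j % 2 != 0:
        m = -m
    return n, m


def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Zernike radial polynomial R_n^|m|(rho)."""
    m = abs(m)
    out = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coef = (
            (-1.0) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        out = out + coef * rho ** (n - 2 * k)
    return out


def zernike_noll(noll_index: int, radius, azimuth) -> np.ndarray:
    """Noll-normalized Zernike polynomial Z_j at polar pupil coordinates.

    Normalization follows Noll: piston is 1 and every mode has unit rms
    over the unit disk, so a coefficient equals the rms wavefront it
    contributes.  Points with ``radius > 1`` evaluate to 0 (outside the
    pupil).
    """
    rho = np.asarray(radius, dtype=float)
    theta = np.asarray(azimuth, dtype=float)
    n, m = noll_to_nm(noll_index)
    norm = math.sqrt(n + 1) if m == 0 else math.sqrt(2.0 * (n + 1))
    radial = _radial_poly(n, m, rho)
    if m == 0:
        val = norm * radial
    elif m > 0:
        val = norm * radial * np.cos(m * theta)
    else:
        val = norm * radial * np.sin(-m * theta)
    return np.where(rho <= 1.0, val, 0.0)


# ---------------------------------------------------------------------------
# Aberration state
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZernikeAberration:
    """Noll-indexed Zernike coefficient map, in radians of phase rms.

    Because the modes are orthonormal over the pupil, the total wavefront
    rms equals the Euclidean norm of the coefficient vector.
    """

    coefficients: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for j, c in self.coefficients.items():
            if int(j) < 1:
                raise InvalidArgumentError(f"Noll index must be >= 1, got {j}")
            clean[int(j)] = float(c)
        object.__setattr__(self, "coefficients", clean)

    @classmethod
    def from_vector(cls, noll_indices, values) -> "ZernikeAberration":
        return cls(dict(zip([int(j) for j in noll_indices], np.asarray(values, float))))

    def coefficient(self, noll_index: int) -> float:
        return self.coefficients.get(int(noll_index), 0.0)

    def as_vector(self, noll_indices) -> np.ndarray:
        return np.array([self.coefficient(j) for j in noll_indices])

    def rms(self) -> float:
        """Total wavefront rms in radians (norm of the coefficient vector)."""
        return float(np.linalg.norm(list(self.coefficients.values()) or [0.0]))

    def scaled(self, factor: float) -> "ZernikeAberration":
        return ZernikeAberration({j: c * factor for j, c in self.coefficients.items()})

    def shifted(self, noll_index: int, delta: float) -> "ZernikeAberration":
        """Return a copy with ``delta`` added to one mode."""
        out = dict(self.coefficients)
        out[int(noll_index)] = out.get(int(noll_index), 0.0) + float(delta)
        return ZernikeAberration(out)

    def __add__(self, other: "ZernikeAberration") -> "ZernikeAberration":
        out = dict(self.coefficients)
        for j, c in other.coefficients.items():
            out[j] = out.get(j, 0.0) + c
        return ZernikeAberration(out)

    def to_nm(self, wavelength: float = DEPLETION_WAVELENGTH_NM) -> dict[int, float]:
        return {j: rad_to_nm(c, wavelength) for j, c in self.coefficients.items()}


def random_unit_aberration(
    noll_indices=DEFAULT_CORRECTION_MODES, seed=None
) -> ZernikeAberration:
    """Draw a unit-norm coefficient vector uniformly on the sphere.

    Scaling the result by a scalar ``c`` gives an aberration of total rms
    ``|c|``; the draw is reproducible from ``seed`` (an int or a Generator).
    """
    indices = [int(j) for j in noll_indices]
    if not indices:
        raise InvalidArgumentError("noll_indices must be non-empty")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=len(indices))
    v /= np.linalg.norm(v)
    return ZernikeAberration.from_vector(indices, v)


# ---------------------------------------------------------------------------
# Optical configuration and PSF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system parameters for the scalar-diffraction model.

    ``image_pixel_size=None`` selects the default of a quarter of the Airy
    disk radius (comfortably above Nyquist for the incoherent cutoff);
    ``pupil_samples`` counts samples across the pupil diameter;
    ``output_shape`` is the PSF support in image pixels.
    """

    emission_wavelength: float = 690.0
    numerical_aperture: float = 1.4
    pupil_samples: int = 256
    image_pixel_size: float | None = None
    output_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not (self.emission_wavelength > 0):
            raise InvalidArgumentError("emission_wavelength must be > 0")
        if not (self.numerical_aperture > 0):
            raise InvalidArgumentError("numerical_aperture must be > 0")
        if self.pupil_samples < 64:
            raise InvalidArgumentError(
                "pupil disk must span >= 64 samples for an accurate PSF"
            )
        if self.image_pixel_size is not None and not (self.image_pixel_size > 0):
            raise InvalidArgumentError("image_pixel_size must be > 0")
        object.__setattr__(self, "output_shape", tuple(int(s) for s in self.output_shape))

    @property
    def pixel_size(self) -> float:
        """Effective image pixel size in nm (quarter-Airy by default)."""
        if self.image_pixel_size is not None:
            return float(self.image_pixel_size)
        return airy_radius(self) / 4.0

    @property
    def nyquist_pixel(self) -> float:
        """Nyquist pitch for the incoherent cutoff 2 NA / lambda, in nm."""
        return self.emission_wavelength / (4.0 * self.numerical_aperture)


@dataclass(frozen=True)
class PointSpreadFunction:
    """Non-negative intensity PSF normalized to unit sum."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if np.any(px < 0) or not np.all(np.isfinite(px)):
            raise InvalidArgumentError("PSF intensities must be finite and >= 0")
        s = px.sum()
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-9):
            raise InvalidArgumentError(f"PSF must sum to 1, got {s}")
        object.__setattr__(self, "pixels", px)


def airy_radius(config: OpticalConfig) -> float:
    """Airy disk radius 0.61 lambda / NA, in nm."""
    return 0.61 * config.emission_wavelength / config.numerical_aperture


class _PupilModel:
    """Cached pupil grid, Zernike basis and zoomed-DFT kernels for a config."""

    def __init__(self, config: OpticalConfig):
        self.config = config
        s = config.pupil_samples
        u = (np.arange(s) - (s - 1) / 2.0) / (s / 2.0)
        ux, uy = np.meshgrid(u, u, indexing="ij")
        self.rho = np.hypot(ux, uy)
        self.theta = np.arctan2(uy, ux)
        self.mask = self.rho <= 1.0
        self.aperture_area = float(self.mask.sum())
        self._basis: dict[int, np.ndarray] = {}
        # zoomed-DFT kernels: image coordinate x_k = (k - n//2) * pixel,
        # pupil spatial frequency f = (NA / lambda) * u
        freq = config.numerical_aperture / config.emission_wavelength
        ny, nx = config.output_shape
        y = (np.arange(ny) - ny // 2) * config.pixel_size
        x = (np.arange(nx) - nx // 2) * config.pixel_size
        self._ky = np.exp(-2j * np.pi * freq * np.outer(y, u))
        self._kx = np.exp(-2j * np.pi * freq * np.outer(x, u))

    def zernike(self, noll_index: int) -> np.ndarray:
        if noll_index not in self._basis:
            z = zernike_noll(noll_index, self.rho, self.theta)
            self._basis[noll_index] = np.where(self.mask, z, 0.0)
        return self._basis[noll_index]

    def phase(self, aberration: ZernikeAberration) -> np.ndarray:
        phi = np.zeros_like(self.rho)
        for j, c in aberration.coefficients.items():
            if c != 0.0:
                phi = phi + c * self.zernike(j)
        return phi

    def field(self, aberration: ZernikeAberration) -> np.ndarray:
        pupil = self.mask * np.exp(1j * self.phase(aberration))
        return self._ky @ pupil @ self._kx.T

    def strehl(self, aberration: ZernikeAberration) -> float:
        """On-axis intensity relative to the unaberrated pupil."""
        pupil_sum = np.sum(np.exp(1j * self.phase(aberration))[self.mask])
        return float(abs(pupil_sum) ** 2 / self.aperture_area**2)


@lru_cache(maxsize=8)
def _pupil_model(config: OpticalConfig) -> _PupilModel:
    return _PupilModel(config)


def psf_incoherent(
    config: OpticalConfig, aberration: ZernikeAberration | None = None
) -> PointSpreadFunction:
    """Aberrated incoherent intensity PSF on the configured pixel grid."""
    if config.pixel_size > 2.0 * config.nyquist_pixel:
        raise UndersampledError(
            f"pixel size {config.pixel_size:.1f} nm undersamples the incoherent "
            f"cutoff by more than 2x (Nyquist pitch {config.nyquist_pixel:.1f} nm)"
        )
    aberration = aberration or ZernikeAberration()
    model = _pupil_model(config)
    intensity = np.abs(model.field(aberration)) ** 2
    return PointSpreadFunction(
        pixels=intensity / intensity.sum(), pixel_size=config.pixel_size
    )


def strehl_ratio(config: OpticalConfig, aberration: ZernikeAberration) -> float:
    """Strehl ratio of the aberrated system (on-axis intensity, <= 1)."""
    return _pupil_model(config).strehl(aberration)


# ---------------------------------------------------------------------------
# Image formation
# ---------------------------------------------------------------------------

def image_forward(
    obj: RasterImage,
    config: OpticalConfig,
    aberration: ZernikeAberration | None = None,
    photon_budget: float | None = None,
    seed=None,
) -> RasterImage:
    """Image a fluorophore map through the aberrated system.

    FFT convolution of the object with the intensity PSF (zero padding, so
    flux leaves only through the frame edges); with a ``photon_budget`` the
    noiseless image is rescaled to that expected total count and Poisson
    sampled with ``seed``.
    """
    if not math.isclose(obj.pixel_size, config.pixel_size, rel_tol=1e-6):
        raise InvalidArgumentError(
            f"object pixel size {obj.pixel_size} nm does not match the optical "
            f"configuration's {config.pixel_size} nm"
        )
    psf = psf_incoherent(config, aberration)
    blurred = signal.fftconvolve(obj.pixels, psf.pixels, mode="same")
    blurred = np.clip(blurred, 0.0, None)
    if photon_budget is not None:
        total = blurred.sum()
        if total <= 0:
            raise InvalidArgumentError("cannot assign a photon budget to a dark image")
        rng = np.random.default_rng(seed)
        blurred = rng.poisson(blurred * (photon_budget / total)).astype(float)
    return RasterImage(pixels=blurred, pixel_size=obj.pixel_size)


def simulated_image_source(
    obj: RasterImage,
    config: OpticalConfig,
    true_aberration: ZernikeAberration,
    photon_budget: float | None = None,
    seed=None,
):
    """Closure emulating a microscope with a hidden specimen aberration.

    The returned callable maps an applied correction to the image formed
    under the residual ``true_aberration + correction``; this is the
    ``image_source`` contract the correction loop consumes.  With a photon
    budget, successive calls draw independent but seed-reproducible noise.
    """
    rng = np.random.default_rng(seed)

    def source(correction: ZernikeAberration) -> RasterImage:
        residual = true_aberration + correction
        return image_forward(
            obj,
            config,
            residual,
            photon_budget=photon_budget,
            seed=rng if photon_budget is not None else None,
        )

    return source
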