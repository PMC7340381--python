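r"""Deformable-mirror control-matrix computation.

Given an influence matrix :math:`H` mapping actuator commands to measured
wavefront-mode coefficients, the command producing a desired wavefront
:math:`y` is the regularized least-squares solution minimizing
:math:`\lVert H u - y \rVert^2 + u^\top \Pi u` with the diagonal penalty
:math:`\Pi = \lambda\,\mathrm{diag}(\beta_1, \dots, \beta_{N_a})`.  The
control matrix is

.. math::

    C = (\Pi + H^\top H)^{-1} H^\top ,

computed through a Cholesky solve of the symmetric positive-definite
normal matrix, never an explicit inverse.  Penalty weights target
actuators outside the effective pupil aperture, whose phase contribution
is too small to constrain: ``beta_i = 1`` penalizes actuator ``i``,
``beta_i = 0`` leaves it free.

A synthetic influence matrix (Gaussian actuator footprints on a square
grid, projected onto the Zernike basis) is provided so the solver is
exercisable without interferometric measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import InvalidArgumentError, SingularCalibrationError
from .optics import zernike_noll

__all__ = [
    "InfluenceMatrix",
    "ActuatorPenalty",
    "control_matrix",
    "gaussian_influence_matrix",
    "DEFAULT_LAMBDA",
]

DEFAULT_LAMBDA = 5e-3


@dataclass(frozen=True)
class InfluenceMatrix:
    """Actuator-to-wavefront response; rows are phase modes (nm per unit
    command), columns are the Na actuators."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.matrix, dtype=float)
        if h.ndim != 2:
            raise InvalidArgumentError(f"influence matrix must be 2-D, got {h.ndim}-D")
        if not np.all(np.isfinite(h)):
            raise InvalidArgumentError("influence matrix contains non-finite entries")
        object.__setattr__(self, "matrix", h)

    @property
    def n_modes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_actuators(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ActuatorPenalty:
    """Per-actuator ridge weights; Pi = lam * diag(betas)."""

    betas: np.ndarray
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 1:
            raise InvalidArgumentError("betas must be a 1-D vector")
        if np.any(b < 0) or np.any(b > 1):
            raise InvalidArgumentError("betas must lie in [0, 1]")
        if self.lam < 0:
            raise InvalidArgumentError(f"lambda must be >= 0, got {self.lam}")
        object.__setattr__(self, "betas", b)
        object.__setattr__(self, "lam", float(self.lam))

    def as_matrix(self) -> np.ndarray:
        return self.lam * np.diag(self.betas)

    @classmethod
    def unpenalized(cls, n_actuators: int) -> "ActuatorPenalty":
        return cls(betas=np.zeros(n_actuators), lam=0.0)


def control_matrix(H: InfluenceMatrix, penalty: ActuatorPenalty | None = None) -> np.ndarray:
    """Regularized pseudo-inverse C = (Pi + H^T H)^-1 H^T.

    With ``lam = 0`` and full column rank this is the Moore–Penrose
    pseudoinverse of H.  Raises :class:`SingularCalibrationError` when the
    normal matrix is not positive definite (rank-deficient H with
    unpenalized null directions).
    """
    if penalty is None:
        penalty = ActuatorPenalty.unpenalized(H.n_actuators)
    if penalty.betas.size != H.n_actuators:
        raise InvalidArgumentError(
            f"penalty has {penalty.betas.size} weights for {H.n_actuators} actuators"
        )
    h = H.matrix
    normal = penalty.as_matrix() + h.T @ h
    try:
        cho = linalg.cho_factor(normal)
    except linalg.LinAlgError as exc:
        raise SingularCalibrationError(
            "Pi + H^T H is not positive definite; add penalty weights or "
            "remove unobservable actuators"
        ) from exc
    # guard against numerically indefinite-but-factorizable matrices
    diag = np.diag(cho[0])
    if np.min(np.abs(diag)) < 1e-10 * np.max(np.abs(diag)):
        raise SingularCalibrationError("normal matrix is singular within tolerance")
    return linalg.cho_solve(cho, h.T)


def gaussian_influence_matrix(
    n_modes: int = 15,
    actuator_grid: tuple[int, int] = (6, 6),
    footprint_sigma: float = 0.35,
    grid_samples: int = 64,
    jitter: float = 0.05,
    seed=None,
) -> tuple[InfluenceMatrix, np.ndarray]:
    """Synthetic DM influence matrix for tests and demos.

    Actuators sit on a regular grid spanning [−1.2, 1.2]² around the unit
    pupil (so a ring of actuators lies outside the aperture, mimicking a
    mirror larger than the imaged pupil); each has a Gaussian footprint of
    width ``footprint_sigma`` whose phase is projected onto Zernike modes
    1..n_modes by disk-mean inner products.  Positions and gains are
    jittered reproducibly from ``seed``.

    Returns the influence matrix and a boolean mask marking actuators
    whose center lies outside the unit pupil (the natural penalty set).
    """
    rng = np.random.default_rng(seed)
    gy, gx = actuator_grid
    cy, cx = np.meshgrid(
        np.linspace(-1.2, 1.2, gy), np.linspace(-1.2, 1.2, gx), indexing="ij"
    )
    centers = np.column_stack([cy.ravel(), cx.ravel()])
    centers = centers + rng.normal(scale=jitter, size=centers.shape)
    gains = 1.0 + rng.normal(scale=jitter, size=len(centers))

    u = np.linspace(-1, 1, grid_samples)
    yy, xx = np.meshgrid(u, u, indexing="ij")
    rho = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    mask = rho <= 1.0
    basis = np.array(
        [zernike_noll(j, rho, theta)[mask] for j in range(1, n_modes + 1)]
    )

    cols = []
    for (ay, ax), g in zip(centers, gains):
        footprint = g * np.exp(
            -((yy - ay) ** 2 + (xx - ax) ** 2) / (2.0 * footprint_sigma**2)
        )
        cols.append(basis @ footprint[mask] / mask.sum())
    H = InfluenceMatrix(np.column_stack(cols))
    outside = np.hypot(centers[:, 0], centers[:, 1]) > 1.0
    return H, outside
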