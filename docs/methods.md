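# Methods

## Imaging model

The simulator implements scalar Fourier optics for an incoherent
(fluorescence) imaging system. The pupil is a uniform disk of numerical
aperture NA carrying a phase `φ = Σ c_j Z_j`, with `Z_j` the Zernike
polynomials in Noll's single-index ordering and normalization (each mode
has unit rms over the disk, so a coefficient is the rms wavefront it
contributes, and the total rms of a multi-mode aberration is the Euclidean
norm of the coefficient vector). The amplitude PSF is the Fourier
transform of `P·e^{iφ}` and the intensity PSF its squared magnitude,
normalized to unit sum; images are the convolution of a fluorophore
density map with the intensity PSF, optionally Poisson-sampled at a
prescribed expected photon total.

Coefficients are stored as phase rms in radians. Conversion to
nanometres, `c·λ/2π`, is done at an explicit wavelength because two
wavelengths matter in practice: the emission wavelength that forms the
image (default 690 nm, NA 1.4) and the depletion wavelength at which bias
amplitudes are quoted (775 nm, where 1 rad ≙ 123 nm).

Numerical choices:

- The PSF field is evaluated with a zoomed (matrix) DFT of the pupil
  directly on the requested image pixel grid, instead of an FFT followed
  by resampling. The pitch is therefore exact for any pixel size, the
  kernels are cached per configuration, and a 64×64 PSF from a 256-sample
  pupil costs two small matrix products (~ms). The default pixel pitch is
  a quarter of the Airy radius `0.61·λ/NA`; configurations undersampling
  the incoherent cutoff by more than 2× are rejected rather than silently
  aliased.
- The PSF support defaults to 64×64 pixels (≈ 4.8 µm at quarter-Airy
  sampling), wide enough that truncation is negligible for aberrations of
  a few radians; object convolution is zero-padded (`fftconvolve`,
  `mode="same"`), so flux is lost only through the frame edge.
- Strehl ratios are computed directly from the pupil sum (on-axis field),
  not from the sampled PSF peak; tests check them against the extended
  Maréchal approximation `exp(−σ²)` for σ ≤ 0.3 rad.

The model is deliberately minimal: no vectorial/high-NA polarization
effects, no depletion-beam photophysics, no confocal pinhole. Both
confocal and STED modes of a real instrument reduce here to "some
incoherent PSF"; the claim under test is about the metric and the
correction loop, not about PSF realism.

## Starlet transform and metric

The starlet is computed separably with `scipy.ndimage.convolve1d` using
the B3-spline taps `(1,4,6,4,1)/16`, dilated at level j by inserting
`2^(j−1)−1` zeros between taps, with symmetric (edge-repeating) boundary
extension — the standard choice that annihilates constants exactly at
every level. All arithmetic is float64; integer photon counts are
promoted on entry. Reconstruction is the telescoping sum
`a_J + Σ d_j`, exact to machine precision; tests compare every plane
against a dense brute-force convolution oracle on small images.

Scale convention: detail level j lives at physical scale
`S_j = δP·2^(j−1)`. With this convention the quarter-Airy pitch at
690 nm / NA 1.4 gives scales 75.2 / 150.3 / 300.6 nm for levels 1–3, and
50 nm pixels give 0.1–0.8 µm for levels 2–5 — the configuration used by
the default metric.

The metric defaults are depth `J = 5` with the finest detail level
skipped (`skip_finest = 1`): level 1 is dominated by Poisson shot noise
in photon-limited images, and skipping it leaves the four scales
0.1–0.8 µm at 50 nm pixels. `skip_finest` is exposed because the
three-element demonstration sweep uses `J = 3, skip_finest = 0`.
`|m′|` is the Euclidean norm. A constant (zero-detail) image raises a
typed `DegenerateImageError` instead of returning a zero vector, so a
scanning loop can drop the sample instead of fitting garbage.

## Correction loop

Per mode: P biases evenly spaced over `[−A, +A]` (A = 1 rad ≙ 123 nm by
default; odd P includes 0) are added to the current correction; one image
and one metric vector per bias; one closed-form least-squares parabola
per retained scale; vertex `−b/2a` as the candidate regardless of
concavity sign (a noise-sensitive fine scale is legitimately *minimized*
at the optimum); score `s = (m_max − m_min)³/(m_max·ε)`; applied
correction = score-weighted mean of candidates. Defaults: P = 7, mode
order (11, 5, 6, 7, 8, 9, 10) — spherical first, since it perturbs the
focal volume most — and one round; a second round seeded with the first
round's correction mimics the confocal-then-STED protocol and costs 2PN
images.

Numerical and design choices, in decreasing order of consequence:

- **Vertex clamping.** Candidate vertices are clamped to the scanned
  range `±A` before combination. A least-squares parabola through a
  peaked response whose optimum sits near the edge of the scan overshoots
  badly (see below); unclamped or loosely clamped vertices occasionally
  *increased* the residual of a mode and poisoned the remaining scans of
  the round. The fit carries no information beyond the scanned interval,
  so the estimate should not leave it.
- **Estimator bias at large per-mode amplitude.** The parabola vertex is
  a consistent estimator only where the response is locally quadratic.
  Fitting 7 samples over ±1 rad of an idealized unit-width peak centered
  at +0.5 puts the vertex near +0.63 — an intrinsic ~25% overshoot that
  any implementation of this estimator shares. At per-mode amplitudes
  ≤ 0.4 rad (the typical share of a 1 rad rms aberration spread over
  7 modes) the bias is negligible; the second round removes what the
  first leaves.
- **ε is the summed squared residual** of the fit (not the mean). The
  distinction only matters when comparing fits with different P.
  Perfect fits are floored at `ε = 1e−12` (metric units²) to keep scores
  finite; curvatures below `1e−10` per rad² flag a fit non-informative
  (score 0, no vertex).
- **Failure handling.** Degenerate images mid-scan are dropped; fewer
  than 3 surviving samples, or all scores zero, skips the mode with a
  zero correction and a logged warning. The loop never aborts, and every
  image consumed is counted, so the P·N budget accounting stays exact.

## Deformable-mirror calibration

`C = (Π + HᵀH)⁻¹Hᵀ` is solved via Cholesky factorization of the normal
matrix (never an explicit inverse); a non-positive-definite normal matrix
raises a typed error. `Π = λ·diag(β)` with λ = 5×10⁻³ by default;
**β_i = 1 penalizes actuator i**, β_i = 0 leaves it free — the intended
use is β = 1 for actuators outside the effective pupil aperture, whose
influence is too weak to constrain. With λ = 0 and full column rank, C
equals the Moore–Penrose pseudoinverse (verified to 1e−8), and for any
penalty `C·y` minimizes `‖Hu − y‖² + uᵀΠu` (verified against a direct
optimizer on small instances). The synthetic influence matrix places
Gaussian actuator footprints on a jittered square grid spanning slightly
beyond the pupil and projects them onto the Zernike basis, so a natural
"outside the aperture" penalty set exists.

## Synthetic specimens, and what passing tests do not show

The generator produces filaments (anti-aliased random walks, 1–3 px wide
after smoothing — fine-scale structure that exercises the finest retained
level at 50–75 nm pixels), sub-resolution beads, and nucleus-like blob
clusters, each over a uniform background, byte-reproducible from a seed.
They emulate the *spatial-scale content* of fluorescence specimens, not
their photophysics: no bleaching, no blinking, no depth-dependent
scattering, and the simulator applies a single field-invariant
aberration. Consequently the green closed-loop tests demonstrate that the
metric and estimator recover known pupil aberrations under the stated
imaging model; they do not demonstrate robustness to spatially varying
aberrations, strong background, or modality-specific PSF shapes — the
situations a real instrument adds.

## Problem sizes and tolerances used in the checks

Closed-loop statistics use a 400×400 filament object at quarter-Airy
pixels, P = 7, one round, ten random unit-rms aberrations (median
residual reported); the metric sweep uses a 256×256 blob object, 21
amplitudes in [−1, 1] rad, three random directions; starlet accuracy is
checked at 512×512 / depth 8 (reconstruction ≤ 1e−9 relative) and against
the dense oracle at ≤ 32×32 (≤ 1e−12 absolute). Zernike orthonormality is
verified on a 512-sample disk grid to 2e−3. The full test suite runs in
about a minute on one CPU; the acceptance script in under half a minute.
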