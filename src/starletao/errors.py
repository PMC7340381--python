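"""Typed error hierarchy.

Every failure mode a caller may want to branch on gets its own class;
all derive from :class:`StarletAOError` so a CLI can catch one type.
"""


class StarletAOError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(StarletAOError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateImageError(StarletAOError, ValueError):
    """The image carries no detail energy (constant or empty); the
    multi-scale metric is undefined for it."""


class UndersampledError(StarletAOError, ValueError):
    """The requested pixel size undersamples the incoherent optical
    cutoff by more than a factor of two; the simulated image would alias."""


class SingularCalibrationError(StarletAOError, ValueError):
    """The regularized normal matrix of the control-matrix problem is not
    positive definite within conditioning tolerance."""


class NoInformationError(StarletAOError, ValueError):
    """Every per-scale fit in a bias scan scored zero; the scan carries no
    usable information about the mode."""
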