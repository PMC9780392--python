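"""Exception hierarchy.

Everything derives from :class:`AquaphotError` (itself a ``ValueError``) so callers
can catch package errors with one clause while plain ``ValueError`` handling still
works.
"""


class AquaphotError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(AquaphotError):
    """A required metadata column is missing or an unknown key was requested."""


class SpectralParseError(AquaphotError):
    """An absorbance cell failed to parse as a number."""


class DuplicateRecordError(AquaphotError):
    """Two rows share the same (condition, day, fruit, position, replicate) key."""


class EmptyRegionError(AquaphotError):
    """A wavelength crop selected no channels."""


class OutOfRangeError(AquaphotError):
    """A requested band lies outside the (padded) wavelength grid."""


class DegenerateSpectrumError(AquaphotError):
    """A spectrum has zero spread and cannot be SNV-transformed."""


class DegenerateChannelError(AquaphotError):
    """A wavelength channel has zero variance across spectra."""


class InsufficientDataError(AquaphotError):
    """Fewer observations than the operation requires."""


class MissingGroupError(AquaphotError):
    """A (condition, day) group required by the computation is absent."""


class MissingBaselineError(AquaphotError):
    """No day-0 weight record exists for the requested fruit."""


class UndefinedForBaselineError(AquaphotError):
    """Daily weight change is undefined at day 0."""


class GapError(AquaphotError):
    """The previous-day weight record is missing."""


class IncompatibleGridError(AquaphotError):
    """Sample wavelengths do not match the model's training grid."""


class UndersizedClassError(AquaphotError):
    """A class has too few spectra for a PCA submodel."""


class NeedTwoClassesError(AquaphotError):
    """SIMCA needs at least two classes."""


class DegenerateModelError(AquaphotError):
    """Class submodels have (numerically) zero self-residual variance."""


class DegenerateResponseError(AquaphotError):
    """The regression response is constant."""


class LimitExceededError(AquaphotError):
    """More latent variables requested than the model allows (limited to 15)."""


class CatalogIntegrityError(AquaphotError):
    """Overlapping ranges in the WAMACS catalog."""


class AxisCollisionError(AquaphotError):
    """Two aquagram axes snap to the same wavelength channel."""


class ConfigError(AquaphotError):
    """Invalid synthetic-data configuration."""
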