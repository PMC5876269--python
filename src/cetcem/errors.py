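"""Exception hierarchy.

Every pipeline stage raises a named subclass of :class:`CetcemError` so that
callers (and the CLI) can report which stage failed.
"""


class CetcemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CetcemError):
    """Invalid phantom specification or run configuration."""


class OutOfRangeError(CetcemError):
    """A requested AP station lies outside the supported extent."""


class STLParseError(CetcemError):
    """Malformed or truncated STL input."""


class MeshValidationError(CetcemError):
    """A surface violates basic mesh invariants (size, finiteness, indices)."""


class AlignmentError(CetcemError):
    """The anatomical frame could not be established."""


class LandmarkError(CetcemError):
    """A tibial landmark could not be located."""


class EdgeExtractionError(CetcemError):
    """Fewer than three usable medial-edge points in a region."""


class InterpolationError(CetcemError):
    """An edge trace is too short to resample."""


class DegenerateFitError(CetcemError):
    """Circle fit attempted on (near-)collinear points."""


class NoOverlapError(CetcemError):
    """No ray from the tibial circle centre intersects the meniscus circle."""


class MeasurementError(CetcemError):
    """A proxy-slice measurement could not be made."""


class DegenerateTestError(CetcemError):
    """A statistical test was called on degenerate data."""


class CohortValidationError(CetcemError):
    """Cohort table fails schema or coverage checks."""
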