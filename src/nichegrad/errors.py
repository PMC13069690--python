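"""Exception hierarchy.

Every error raised on bad user input derives from :class:`NichegradError`
so the CLI can map them uniformly to exit code 2.
"""


class NichegradError(Exception):
    """Base class for all nichegrad errors."""


class SchemaError(NichegradError):
    """A required column or file component is missing."""


class ValidationError(NichegradError):
    """Input parsed but violates an invariant (duplicates, NaN, shape mismatch)."""


class ParameterError(NichegradError):
    """A parameter value is out of its admissible range."""


class GeometryError(NichegradError):
    """Degenerate or invalid geometry (collinear points, zero-length curve, ...)."""


class AlignmentError(NichegradError):
    """Coordinate and expression inputs share no cells."""


class InsufficientDataError(NichegradError):
    """Too few cells/replicates/distinct values for the requested statistic."""
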