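"""Exception hierarchy for the nailfold pipeline.

Every stage raises a subclass of :class:`NailfoldError` so the pipeline
driver can isolate per-digit failures without masking programming errors.
"""


class NailfoldError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(NailfoldError, ValueError):
    """A parameter violates a precondition (non-positive length, bad range...)."""


class GeometryError(NailfoldError):
    """Generated or requested geometry does not fit the image frame."""


class RegistrationError(NailfoldError):
    """Pairwise frame registration failed; carries the nominal offset fallback."""

    def __init__(self, message: str, fallback_offset=None):
        super().__init__(message)
        self.fallback_offset = fallback_offset


class TraceError(NailfoldError):
    """Path tracing could not start or proceed from the given apex."""


class WidthMeasurementError(NailfoldError):
    """Too many path points had unmeasurable width profiles."""


class FlowError(NailfoldError):
    """Velocity estimation failed for a capillary (e.g. apex never visible)."""


class SummaryError(NailfoldError):
    """A capillary had too few measurable points to summarise."""


class SchemaError(NailfoldError):
    """An input table is missing required columns or labels."""


class InvalidInputError(NailfoldError, ValueError):
    """Empty or degenerate input where data is required."""
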