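"""Exception hierarchy for the inter-limb coordination pipeline.

Every stage raises a subclass of :class:`InterlimbError` so callers can
distinguish bad configuration from bad data from numerical failure.
"""


class InterlimbError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InterlimbError):
    """Invalid analysis or generator configuration (non-finite, out of range)."""


class SchemaError(InterlimbError):
    """A required column or marker is missing from an input file."""


class FormatError(InterlimbError):
    """Input file is structurally readable but violates the format contract
    (e.g. non-uniform sampling)."""


class GapError(InterlimbError):
    """Missing (NaN) samples in a marker trajectory."""


class DegenerateInputError(InterlimbError):
    """Input carries no usable signal (constant series, zero variance)."""


class InsufficientDataError(InterlimbError):
    """Too few samples or events to compute the requested quantity."""


class EventContractError(InterlimbError):
    """Gait events violate the alternating left/right contract."""


class CalibrationError(InterlimbError):
    """Radius bisection failed to bracket the target recurrence rate."""


class NoLinesError(InterlimbError):
    """A recurrence plot contains no diagonal line of the minimum length."""


class NoMatchesError(InterlimbError):
    """Cross sample entropy found zero template matches; the tolerance r is
    too small for the data."""
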