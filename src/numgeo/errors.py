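"""Exception hierarchy for the numgeo pipeline.

Every stage raises a subclass of :class:`NumgeoError` so callers (and the
CLI) can distinguish configuration mistakes from degenerate data.
"""


class NumgeoError(Exception):
    """Base class for all numgeo errors."""


class ConfigurationError(NumgeoError):
    """Invalid configuration (bad correlation matrix, protocol sizes, ...)."""


class ValidationError(NumgeoError):
    """Input data violates a schema or a documented bound."""


class EmptyDataError(NumgeoError):
    """An operation received no data."""


class InsufficientDataError(NumgeoError):
    """Fewer observations than the configured minimum."""


class DegenerateFitError(NumgeoError):
    """A fit cannot be identified (e.g. all responses identical)."""


class DegenerateTestError(NumgeoError):
    """A statistical test is undefined on this input (zero variance)."""


class CatalogError(NumgeoError):
    """Unknown spatial-sequence name."""


class PowerUnreachableError(NumgeoError):
    """Requested power cannot be reached within the sample-size ceiling."""
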