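"""Exception hierarchy shared across the package."""


class BarrierAssayError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(BarrierAssayError):
    """A track table could not be parsed; the message names the offending line."""


class IntegrityError(BarrierAssayError):
    """Structurally valid input violates a data-model invariant (e.g. duplicate frames)."""


class UnitError(BarrierAssayError):
    """An operation received coordinates in the wrong unit system."""


class ConfigurationError(BarrierAssayError):
    """An arena or run configuration is missing or inconsistent."""


class EmptyProfileError(BarrierAssayError):
    """No tracked midpoints fall inside the binned range."""


class InsufficientDataError(BarrierAssayError):
    """A statistical routine was given fewer observations than it requires."""


class GridError(BarrierAssayError):
    """Profiles to be compared do not share a common bin grid."""


class ValidationError(BarrierAssayError):
    """A simulation configuration field is out of range or inconsistent."""


class UndefinedIndexError(BarrierAssayError):
    """A ratio statistic is undefined because its denominator is zero."""
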