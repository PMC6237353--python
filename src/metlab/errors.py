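"""Exception hierarchy shared across the package."""


class MetlabError(Exception):
    """Base class for all package errors."""


class SchemaError(MetlabError):
    """A required column or field is missing or malformed."""


class ValidationError(MetlabError):
    """Values violate a type invariant (duplicates, negatives, bad enums)."""


class ParseError(MetlabError):
    """A cell or a name could not be parsed; carries row/token context."""


class FitError(MetlabError):
    """Too few points or a degenerate design for a calibration fit."""


class InversionError(MetlabError):
    """Calibration inversion found no usable root for a response."""


class AmbiguousInversionError(InversionError):
    """More than one calibration root lies inside the calibrated range."""


class ConfigurationError(MetlabError):
    """A correction strategy or CLI configuration is not applicable."""
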