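"""Exception hierarchy shared across the package."""


class QtcError(ValueError):
    """Base class for all qtckit errors."""


class DomainError(QtcError):
    """An input is outside the mathematical domain of a formula (e.g. RR <= 0)."""


class ValidationError(QtcError):
    """A record or table fails a physiological / consistency check."""


class SchemaError(QtcError):
    """An input file is missing required columns or has a malformed header."""
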