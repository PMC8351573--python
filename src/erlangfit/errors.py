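"""Exception hierarchy shared across the package."""


class ErlangFitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ErlangFitError, ValueError):
    """A distribution parameter violates its family's constraints."""


class DomainError(ErlangFitError, ValueError):
    """The density was requested at a point where it is not finite."""


class ParseError(ErlangFitError, ValueError):
    """An age-group label or table cell could not be interpreted."""


class UnsupportedBinError(ParseError):
    """Open-ended age bins ("85+ years") have no defensible midpoint."""


class SchemaError(ErlangFitError, ValueError):
    """An input table is missing required columns."""


class DegenerateDataError(ErlangFitError, ValueError):
    """The observed series cannot constrain a fit (all-zero or constant)."""


class ConfigError(ErlangFitError, ValueError):
    """A grid or run configuration is inconsistent with the chosen family."""
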