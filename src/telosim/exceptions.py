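"""Exception hierarchy for telosim."""


class TelosimError(Exception):
    """Base class for all telosim errors."""


class ParameterError(TelosimError, ValueError):
    """A simulation or experiment parameter is invalid; names the offending field."""


class DomainError(TelosimError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UndefinedStatisticError(TelosimError, ValueError):
    """A statistic is undefined for the given input (e.g. zero total variance)."""


class FormatError(TelosimError, ValueError):
    """A file or table does not conform to the expected format."""


class ConfigError(TelosimError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
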