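"""Exception types shared across the package."""


class EmtdynError(Exception):
    """Base class for all package-specific errors."""


class CircuitParseError(EmtdynError):
    """Raised when a topology file is malformed; the message names the line."""


class InvalidParameterError(EmtdynError, ValueError):
    """Raised for kinetic parameters outside their admissible domain."""


class ConfigError(EmtdynError, ValueError):
    """Raised for inconsistent simulation or estimation configuration."""


class EmptyEnsembleError(EmtdynError):
    """Raised when an ensemble run produced no usable steady states."""


class DegenerateEnsembleError(EmtdynError):
    """Raised when a node has zero dispersion and cannot be z-scored."""


class UnderdeterminedError(EmtdynError):
    """Raised when too few informative grids exist to identify the
    transition matrix for a frame interval."""
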