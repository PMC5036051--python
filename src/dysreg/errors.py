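"""Exception hierarchy shared across the pipeline stages."""


class DysregError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DysregError, ValueError):
    """Invalid configuration (counts, probabilities, thresholds out of range)."""


class FormatError(DysregError, ValueError):
    """Malformed input file (bad BED line, duplicate identifiers, ...)."""


class AlignmentError(DysregError, ValueError):
    """Matrices cannot be placed on a shared sample/gene space."""


class InputError(DysregError, ValueError):
    """Invalid in-memory input to a statistical operation."""


class ConvergenceError(DysregError, RuntimeError):
    """Iterative solver failed to reach its tolerance."""
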