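"""Exception types shared across the pipeline."""


class PvSignalError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PvSignalError, ValueError):
    """A scenario or pipeline configuration value is invalid."""


class InputError(PvSignalError, ValueError):
    """An input file is missing, malformed, or has unexpected headers."""


class ZeroMarginError(PvSignalError, ValueError):
    """A 2x2 margin is zero; apply the Haldane-Anscombe correction first."""


class DomainError(PvSignalError, ValueError):
    """A statistic was requested outside its mathematical domain."""
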