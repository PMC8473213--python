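"""Exception hierarchy shared across the package."""


class EEGStressError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EEGStressError, ValueError):
    """A configuration object violates one of its invariants."""


class DomainError(EEGStressError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateSignalError(EEGStressError, ValueError):
    """A signal is degenerate for the requested statistic (e.g. zero variance)."""


class ParseError(EEGStressError, ValueError):
    """A recording or table file could not be parsed."""
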