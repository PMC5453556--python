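"""Exception hierarchy shared across the toolkit.

Every error raised deliberately by this package derives from
:class:`CrypticScreenError`, so callers (and the CLI) can distinguish
domain failures from programming bugs.
"""


class CrypticScreenError(Exception):
    """Base class for all toolkit errors."""


class ParseError(CrypticScreenError):
    """A structure or table file could not be parsed."""


class ConfigError(CrypticScreenError):
    """Invalid parameters or an inconsistent configuration."""


class ContractError(CrypticScreenError):
    """A documented precondition of an operation was violated."""


class ResourceError(CrypticScreenError):
    """An operation would exceed a configured resource budget."""


class FitError(CrypticScreenError):
    """A nonlinear fit failed to converge or is degenerate."""


class InsufficientDataError(CrypticScreenError):
    """Too few data points for the requested analysis."""


class FixtureError(CrypticScreenError):
    """A synthetic-fixture specification cannot be realized."""
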