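"""Exception hierarchy shared across the package."""


class HistosynthError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(HistosynthError, ValueError):
    """An argument violates an operation's precondition."""


class InvalidFormat(HistosynthError, ValueError):
    """Data on disk violates a format contract (e.g. a non-square tile)."""


class DegenerateInput(HistosynthError, ValueError):
    """Input on which a statistic is undefined (e.g. zero within-cluster scatter)."""


class NumericError(HistosynthError, ArithmeticError):
    """A computation produced or received non-finite values."""
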