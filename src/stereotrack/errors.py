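"""Exception types shared across the package."""


class StereotrackError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(StereotrackError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDataError(StereotrackError, ValueError):
    """Input data breaks an invariant (e.g. a zero-height box)."""


class UndefinedStatisticError(StereotrackError, ValueError):
    """A statistic is undefined for this input (zero denominator, constant series)."""


class NumericalError(StereotrackError, ArithmeticError):
    """A numerical routine failed (singular matrix, degenerate spectrum)."""


class ParseError(StereotrackError, ValueError):
    """A data file could not be parsed; the message names the line number."""
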