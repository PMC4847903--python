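"""Exception hierarchy shared across the package."""


class TcChartError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TcChartError, ValueError):
    """Input violates a documented precondition or type invariant."""


class SaturationError(TcChartError):
    """All chambers positive: the Poisson occupancy estimate is unbounded."""


class UndefinedRatioError(TcChartError, ZeroDivisionError):
    """Denominator concentration or signal count is zero."""


class DomainError(TcChartError, ValueError):
    """Parameter outside the range the model derivation covers."""
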