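"""Exception hierarchy.

All package errors derive from :class:`SasTubesError` so callers can catch
library failures with a single except clause while still letting genuine
programming errors (TypeError etc.) propagate.
"""


class SasTubesError(Exception):
    """Base class for all sastubes errors."""


class CurveFormatError(SasTubesError, ValueError):
    """A curve file could not be parsed (e.g. fewer than two numeric columns)."""


class EmptyDataError(SasTubesError, ValueError):
    """No valid data rows survived parsing and filtering."""


class EmptyWindowError(SasTubesError, ValueError):
    """A q-window selection left no data points."""


class DegenerateContrastError(SasTubesError, ValueError):
    """All shell contrasts vanish; the normalization constant is undefined."""


class ModelDomainError(SasTubesError, ValueError):
    """Model parameters violate a validity condition of the expression used."""


class AccuracyError(SasTubesError, RuntimeError):
    """A quadrature failed to reach the requested tolerance.

    Carries the best available estimate in ``estimate``.
    """

    def __init__(self, message, estimate=None):
        super().__init__(message)
        self.estimate = estimate
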