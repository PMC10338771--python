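"""Exception hierarchy shared by all ptvmargin modules."""


class PtvMarginError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PtvMarginError):
    """A tracking-log file violates the CSV schema.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row


class ConfigurationError(PtvMarginError):
    """Invalid configuration value (unknown enum, out-of-range parameter, ...)."""


class InsufficientDataError(PtvMarginError):
    """Not enough samples/fractions to compute the requested statistic."""


class InsufficientCohortError(InsufficientDataError):
    """Cohort-level statistic requested with fewer than two patients."""


class UndefinedCorrelationError(PtvMarginError):
    """Pearson correlation requested on a constant marginal."""


class DomainError(PtvMarginError, ValueError):
    """Numeric input outside the admissible domain of a formula."""


class ZeroVarianceError(PtvMarginError):
    """All observations identical across all groups; F-test undefined."""


class ScenarioNotApplicableError(PtvMarginError):
    """A validation scenario cannot be run on the given fractions."""
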