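"""Exception hierarchy shared across the package."""


class NestheatError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NestheatError, ValueError):
    """An input violates a documented precondition."""


class DegenerateSeriesError(InvalidInputError):
    """An isotope time series cannot yield a turnover estimate."""


class InvalidEnrichmentError(InvalidInputError):
    """Background-corrected enrichment is non-positive (background exceeds sample)."""


class ConventionViolationError(NestheatError):
    """A physical sign contract was violated (implementation/sign error guard)."""


class InsufficientCalibrationError(InvalidInputError):
    """Too few calibration pairs or too narrow a temperature span."""


class CoverageError(InvalidInputError):
    """A date range is not fully covered by daily records."""

    def __init__(self, msg, gaps=None):
        super().__init__(msg)
        self.gaps = list(gaps or [])


class AlignmentError(NestheatError):
    """Two timestamped series share no records within tolerance."""


class OverlapError(InvalidInputError):
    """Two bout/recess intervals overlap within one nest-day."""

    def __init__(self, msg, pair=None):
        super().__init__(msg)
        self.pair = pair


class DegeneratePredictorError(InvalidInputError):
    """A predictor has zero variance and cannot be standardized."""


class SingularityError(NestheatError):
    """A design matrix is singular."""


class ConvergenceError(NestheatError):
    """Iterative fitting failed to converge."""


class ComparabilityError(InvalidInputError):
    """Candidate models were not fitted on identical rows."""


class NoBreakpointError(NestheatError):
    """No admissible two-segment split exists."""


class UndefinedThresholdError(NestheatError):
    """A logistic threshold is undefined (zero slope)."""


class ConfigError(NestheatError):
    """Pipeline configuration invalid (CLI exit code 2)."""


class DataError(NestheatError):
    """Pipeline input data invalid at run time (CLI exit code 3)."""
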