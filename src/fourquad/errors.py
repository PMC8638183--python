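"""Exception hierarchy for fourquad."""


class FourQuadError(Exception):
    """Base class for all fourquad errors."""


class ConfigurationError(FourQuadError):
    """Invalid analysis configuration or malformed input data."""


class EstimationError(FourQuadError):
    """Parameter estimation is impossible (e.g. fewer than two subjects)."""


class UndefinedRateError(FourQuadError):
    """A concordance rate is undefined for the given data.

    Typically raised when every point (or every subject) falls inside the
    exclusion zone, so the conditioning event has empty support.  The counts
    that led to the degenerate denominator are attached when available.
    """

    def __init__(self, message, **counts):
        super().__init__(message)
        self.counts = counts


class EvaluationError(FourQuadError):
    """ROC/AUC evaluation cannot proceed (e.g. single-class labels)."""


class NumericalError(FourQuadError):
    """Numerical failure in the multivariate-normal integration."""
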