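"""Exception hierarchy shared across the package."""


class ScoreBiasError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ScoreBiasError):
    """A required column is missing or a cell cannot be parsed."""


class CollinearityError(ScoreBiasError):
    """The design matrix contains an exact (or near-exact) linear dependence.

    Parameters
    ----------
    columns : list of str
        Names of the columns implicated in the dependence.
    """

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message or f"collinear design: columns {sorted(self.columns)} "
            "are linearly dependent"
        )


class EstimationError(ScoreBiasError):
    """A model cannot be estimated on the given data (e.g. no events)."""


class ConvergenceError(ScoreBiasError):
    """The iterative fitter failed to converge within its iteration budget."""


class RoleSpecError(ScoreBiasError):
    """The variable-role specification for a two-stage analysis is invalid."""


class InfiniteBiasError(ScoreBiasError):
    """The instrument-to-exposure coefficient is (numerically) zero, so the
    omitted-instrument bias delta/d is unbounded."""


class ExperimentError(ScoreBiasError):
    """Too many replicate-level failures in a Monte Carlo experiment."""
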