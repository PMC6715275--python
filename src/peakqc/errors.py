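"""Exception hierarchy for peakqc.

All computational failures derive from :class:`PeakQcError` so the CLI can
map them to a single non-zero exit code while argument/usage problems stay
with the argument parser.
"""


class PeakQcError(Exception):
    """Base class for all peakqc computation errors."""


class BedParseError(PeakQcError):
    """A BED line could not be parsed; carries the offending line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class UndefinedEstimatorError(PeakQcError):
    """A population-size estimator is undefined for the given frequencies
    (e.g. Chao with f2 = 0)."""

    def __init__(self, estimator: str, reason: str):
        self.estimator = estimator
        super().__init__(f"estimator '{estimator}' undefined: {reason}")


class UndefinedMetricError(PeakQcError):
    """FPCM (or another metric) cannot be computed from the given
    frequencies; the message recommends direct inspection of the data."""


class DegenerateInputError(PeakQcError):
    """Input is structurally valid but degenerate for the requested
    computation (all pairwise overlaps zero, fewer than three estimates
    for the outlier test, ...)."""


class ConvergenceError(PeakQcError):
    """Numerical optimisation failed to converge; carries the best iterate."""

    def __init__(self, message: str, best_iterate=None):
        self.best_iterate = best_iterate
        super().__init__(message)


class SimulationCapacityError(PeakQcError):
    """Non-overlapping placement of simulated peaks failed after bounded
    retries; a larger genome_length is the usual fix."""
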