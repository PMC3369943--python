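"""Exception hierarchy for spikemaxent."""


class SpikeMaxEntError(Exception):
    """Base class for all spikemaxent errors."""


class InvalidParameterError(SpikeMaxEntError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateMarginalError(SpikeMaxEntError, ValueError):
    """A marginal distribution has zero variance (all mass at one point)."""


class FeasibilityError(SpikeMaxEntError, ValueError):
    """The requested correlation is not attainable for the given marginals.

    Carries the attainable range so callers can clip or report it.
    """

    def __init__(self, message: str, rho_min: float | None = None,
                 rho_max: float | None = None):
        super().__init__(message)
        self.rho_min = rho_min
        self.rho_max = rho_max


class ConvergenceError(SpikeMaxEntError, RuntimeError):
    """An iterative solver failed to reach its tolerance.

    ``residuals`` holds the final constraint residuals for diagnosis.
    """

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class CalibrationError(SpikeMaxEntError, ValueError):
    """Root bracketing failed while calibrating a copula parameter."""


class LabelingError(SpikeMaxEntError, ValueError):
    """Stimulus labels are missing or inconsistent with the reference ensemble."""


class InsufficientDataError(SpikeMaxEntError, ValueError):
    """Too few observations (e.g. spikes) to run the requested procedure."""
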