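"""Exception hierarchy shared across the package."""


class SpectralDCMError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpectralDCMError, ValueError):
    """A parameter vector or model definition failed validation."""


class NonConvergenceError(SpectralDCMError, RuntimeError):
    """An iterative solver exhausted its budget without converging."""


class StabilityError(SpectralDCMError, RuntimeError):
    """A fixed point is linearly unstable (distinct from non-convergence)."""


class InstabilityError(SpectralDCMError, RuntimeError):
    """A time-domain simulation diverged.

    Attributes
    ----------
    time_s : float
        Simulation time at which the state first exceeded the blow-up bound.
    """

    def __init__(self, message: str, time_s: float | None = None):
        super().__init__(message)
        self.time_s = time_s


class ConditioningError(SpectralDCMError, RuntimeError):
    """A regression or design matrix is rank deficient / ill conditioned."""


class FormatError(SpectralDCMError, ValueError):
    """An on-disk artefact violates the expected format."""


class ConfigError(SpectralDCMError, ValueError):
    """A run configuration is invalid (unknown keys, inconsistent values)."""
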