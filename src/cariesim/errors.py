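"""Exception types shared across the package."""


class CariesimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CariesimError, ValueError):
    """An input configuration violates a documented invariant."""


class CalibrationError(CariesimError, RuntimeError):
    """Calibration failed to reach its tolerance within the iteration budget."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class NotCalibratedError(CariesimError, RuntimeError):
    """A scenario run was requested with an uncalibrated risk model."""


class PopulationMismatchError(CariesimError, ValueError):
    """Incremental comparison attempted across different populations."""
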