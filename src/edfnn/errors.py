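"""Exception types raised by the gait-percent pipeline."""


class EDFNNError(Exception):
    """Base class for all package errors."""


class InvalidSignalError(EDFNNError, ValueError):
    """A sensor series contains NaN/inf or violates its physical range."""


class DegenerateCycleError(EDFNNError, ValueError):
    """A gait cycle is too short to carry a percent ramp (duration < 2 samples)."""


class InsufficientDataError(EDFNNError, ValueError):
    """The signal is too short for the requested delay window and forecast horizon."""


class ConfigurationError(EDFNNError, ValueError):
    """A delay/window configuration is internally inconsistent."""


class TrainingDivergenceError(EDFNNError, RuntimeError):
    """Training cost became non-finite."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite cost) at epoch {epoch}")


class SplitError(EDFNNError, ValueError):
    """Too few gait cycles to produce non-empty train and validation parts."""


class UndefinedRSquaredError(EDFNNError, ValueError):
    """R-squared is undefined because the ground truth is constant."""
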