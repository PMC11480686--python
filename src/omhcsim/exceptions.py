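"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a profile, policy, or simulation config is invalid or
    when a calibration target is unreachable with the given parameters."""


class CalibrationError(RuntimeError):
    """Raised when iterative outcome-model calibration fails to converge;
    carries the residual table for diagnosis."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals
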