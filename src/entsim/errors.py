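"""Exception types shared across the package."""


class EntsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EntsimError):
    """Invalid or inconsistent model/protocol configuration."""


class InputError(EntsimError, ValueError):
    """Invalid runtime input (non-finite voltage, bad dt, ...)."""


class StateCorruptionError(EntsimError):
    """A state variable left its admissible range (gate outside [0, 1], g < 0)."""


class IntegrationError(EntsimError):
    """Numerical divergence during membrane integration."""

    def __init__(self, message: str, t_ms: float | None = None):
        super().__init__(message)
        self.t_ms = t_ms


class CalibrationError(EntsimError):
    """Synaptic-weight calibration failed to bracket a threshold."""
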