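"""Exception hierarchy for configuration, calibration and numerical failures."""


class CranioflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CranioflowError):
    """Malformed, incomplete or internally inconsistent network configuration."""


class CalibrationError(CranioflowError):
    """Derived-parameter calibration cannot be completed."""


class ConstraintError(CranioflowError):
    """Ill-posed linear constraint specification (e.g. rank-deficient rows)."""


class IntegrationError(CranioflowError):
    """Time integration failed before reaching the requested horizon."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class SteadyStateError(CranioflowError):
    """Steady-state search did not converge to the requested residual."""


class ExperimentError(CranioflowError):
    """A shipped numerical experiment failed (with diagnostics attached)."""
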