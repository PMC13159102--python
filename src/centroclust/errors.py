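"""Exception hierarchy shared across the package."""


class CentroclustError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CentroclustError, ValueError):
    """Invalid simulation or analysis configuration."""


class NumericalInstabilityError(CentroclustError, FloatingPointError):
    """A state variable became non-finite during integration.

    Carries the name of the offending entity so the failing run can be
    diagnosed from logs alone.
    """

    def __init__(self, entity: str, time_s: float):
        self.entity = entity
        self.time_s = time_s
        super().__init__(
            f"non-finite position detected in {entity} at t={time_s:.3f} s"
        )


class MissingSnapshotError(CentroclustError, KeyError):
    """A required snapshot time is absent from a simulation record."""

    def __init__(self, time_s: float):
        self.time_s = time_s
        super().__init__(f"no snapshot recorded at t={time_s:g} s")


class FitError(CentroclustError, RuntimeError):
    """Curve fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, p0=None, residuals=None):
        self.p0 = p0
        self.residuals = residuals
        super().__init__(message)


class GridError(CentroclustError, ValueError):
    """A condition/parameter grid is empty or incomplete."""
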