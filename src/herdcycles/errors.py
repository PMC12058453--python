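"""Exception types shared across herdcycles modules."""


class HerdcyclesError(Exception):
    """Base class for package errors."""


class InvalidParameterError(HerdcyclesError, ValueError):
    """A model or configuration parameter violates its constraints."""


class SimulationError(HerdcyclesError, RuntimeError):
    """The ODE integrator failed; carries the last valid time reached."""

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class NumericalStateError(HerdcyclesError, ValueError):
    """A state vector contains NaNs or is negative beyond tolerance."""


class DegenerateSeriesError(HerdcyclesError, ValueError):
    """A time series is constant or otherwise unusable for spectral analysis."""


class FitError(HerdcyclesError, RuntimeError):
    """A statistical fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(HerdcyclesError, ValueError):
    """An input file violates its expected schema."""
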