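"""Exception hierarchy shared across the package."""


class AstrocaError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AstrocaError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class SolverError(AstrocaError, RuntimeError):
    """The ODE solver failed to advance; carries the failing time."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class NonFiniteStateError(SolverError):
    """A state component became NaN or infinite during integration."""


class NegativeConcentrationError(SolverError):
    """A concentration-like state dropped below the -1e-9 guard.

    The integrator never clamps: silently projecting back onto the positive
    orthant would change the dynamics, so the run fails loudly instead.
    """


class TooFewPeaksError(AstrocaError):
    """Fewer than three qualifying peaks: no period can be estimated."""


class NonOscillatoryError(AstrocaError):
    """A trajectory required to be oscillatory is not."""


class ConfigError(AstrocaError, ValueError):
    """Invalid run configuration (unknown parameter override, bad value)."""


class SweepError(AstrocaError, RuntimeError):
    """A sweep member failed; carries the offending input value."""

    def __init__(self, message: str, value: float):
        super().__init__(message)
        self.value = value
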