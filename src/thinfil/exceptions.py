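"""Exception hierarchy.

Every error raised by the package derives from :class:`ThinfilError`, so callers
(and the CLI) can map failures to machine-readable categories.
"""


class ThinfilError(Exception):
    """Base class for all package errors."""

    category = "error"


class ParameterError(ThinfilError, ValueError):
    """A constant, rate, or option violates its admissible range."""

    category = "parameter"


class DomainError(ThinfilError, ValueError):
    """An evaluation point lies outside the function's domain (e.g. t < 0)."""

    category = "domain"


class ValidationError(ThinfilError, ValueError):
    """Configuration validation failed; carries every offending field."""

    category = "validation"

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration: " + "; ".join(self.errors))


class StateError(ThinfilError, RuntimeError):
    """A state vector left the physical simplex beyond round-off slack."""

    category = "state"


class ConvergenceError(ThinfilError, RuntimeError):
    """A steady-state relaxation failed to meet its residual criterion."""

    category = "convergence"

    def __init__(self, message, residual_norm=None):
        super().__init__(message)
        self.residual_norm = residual_norm


class IntegrationError(ThinfilError, RuntimeError):
    """The ODE solver failed; carries the last successfully reached time."""

    category = "integration"

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time


class ComparabilityError(ThinfilError, ValueError):
    """Two series/trajectories are not on comparable grids or stimuli."""

    category = "comparability"


class FitDomainError(ThinfilError, ValueError):
    """A curve does not span the transition needed for a Hill fit."""

    category = "fit_domain"


class UndefinedFractionError(ThinfilError, ValueError):
    """An area fraction is undefined because the reference integral is zero."""

    category = "undefined_fraction"


class DegenerateSeriesError(ThinfilError, ValueError):
    """A constant series cannot be min-max normalized."""

    category = "degenerate_series"
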