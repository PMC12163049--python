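"""Exception hierarchy for the remf package."""


class RemfError(Exception):
    """Base class for all remf errors."""


class DimensionError(RemfError):
    """Array shapes are inconsistent with the declared system dimensions."""


class IntegrationError(RemfError):
    """The integrator produced a non-finite state or derivative."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class StabilityError(RemfError):
    """An explicit transport step was requested above the stability bound."""

    def __init__(self, message: str, dt_max: float | None = None):
        super().__init__(message)
        self.dt_max = dt_max


class InvalidParameterError(RemfError):
    """A parameter violates its declared domain (sign, range, shape)."""


class InvalidInterventionError(RemfError):
    """An intervention field is negative or otherwise inadmissible."""


class InfeasibleConfigurationError(RemfError):
    """The feasible set of the optimization problem is empty."""


class DegenerateWeightsError(RemfError):
    """Objective weights collapsed to the zero vector."""


class DegenerateAllocationError(RemfError):
    """All stakeholder allocation weights are zero."""


class UndefinedRatioError(RemfError):
    """Cost-benefit ratio requested with zero spend."""


class ConfigError(RemfError):
    """Scenario configuration failed to parse or validate.

    The message names the offending key path.
    """
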