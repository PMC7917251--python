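"""Exception hierarchy.

All domain errors derive from :class:`MinmodError` so callers (and the CLI)
can distinguish bad input / failed computation from programming errors.
"""


class MinmodError(Exception):
    """Base class for all errors raised by minmod."""


class ParameterError(MinmodError, ValueError):
    """A model parameter violates its physical or mathematical constraints."""


class InputDomainError(MinmodError, ValueError):
    """Requested evaluation outside the domain covered by the inputs
    (e.g. simulation times beyond the insulin record)."""


class DataError(MinmodError, ValueError):
    """A data record is malformed or insufficient for the requested operation."""


class ConfigError(MinmodError, ValueError):
    """Inconsistent or invalid configuration."""


class NumericalError(MinmodError, RuntimeError):
    """A numerical routine failed (solver breakdown, non-finite values)."""


class ConvergenceError(NumericalError):
    """An iterative computation did not reach its convergence criterion.

    Attributes
    ----------
    achieved : float or None
        Fraction of the convergence criterion that was reached, when known.
    """

    def __init__(self, message, achieved=None):
        super().__init__(message)
        self.achieved = achieved


class IdentifiabilityError(MinmodError, RuntimeError):
    """Parameters cannot be uniquely determined from the data
    (singular or rank-deficient Jacobian at the optimum)."""


class InconsistentDataError(DataError):
    """Observations contradict the model beyond what noise can explain."""
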