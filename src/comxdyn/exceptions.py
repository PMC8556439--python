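"""Exception hierarchy shared across the package."""


class ComxdynError(Exception):
    """Base class for all comxdyn-specific errors."""


class ValidationError(ComxdynError, ValueError):
    """Input data violates a structural invariant (schema, monotonicity, sign)."""


class InsufficientDataError(ComxdynError, ValueError):
    """Too few observations to perform the requested computation."""


class InsufficientVariationError(InsufficientDataError):
    """Observations carry no variation, so a curve cannot be identified."""


class DomainError(ComxdynError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class NoSteadyStateError(DomainError):
    """The model has no finite steady state for the given parameters."""


class InfeasibleTargetError(DomainError):
    """A generator target cannot be realised with non-negative raw readings."""


class ConvergenceError(ComxdynError, RuntimeError):
    """An iterative solver failed to converge.

    The best iterate reached is attached as ``best`` so callers can inspect it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
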