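"""Exception hierarchy shared across the package.

All input-validation failures derive from :class:`InvalidInputError` (CLI exit
code 2); failures of numerical procedures derive from
:class:`NumericalError` (CLI exit code 3).
"""


class SdepError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SdepError, ValueError):
    """An argument violates a documented precondition."""


class DomainError(InvalidInputError):
    """A coordinate lies outside the physically meaningful domain
    (e.g. a sphere center closer to the wall than its radius)."""


class ModelInfeasibleError(InvalidInputError):
    """A composition-space model occupies more than 100% of space somewhere."""


class NumericalError(SdepError, RuntimeError):
    """A numerical procedure failed (non-convergence, no bracketing root...)."""


class NoCrossingError(NumericalError):
    """A threshold crossing was requested outside the range of the curve."""


class ConvergenceError(NumericalError):
    """An iterative solver or sampler did not meet its stopping criterion."""


class ExclusionBelowResolutionError(NumericalError):
    """The fitted polymer profile never drops to half its bulk density
    above the plane of charge (interaction strength E0 <= ln 2)."""
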