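"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`BindgateError`,
so callers (and the CLI) can distinguish modeling/analysis failures from bugs.
"""


class BindgateError(Exception):
    """Base class for all bindgate errors."""


class RoleError(BindgateError, ValueError):
    """A ligand was used in a role (orthosteric/allosteric) it does not have."""


class CapacityError(BindgateError, ValueError):
    """Exhaustive microstate enumeration would exceed the supported size."""


class ComputationError(BindgateError, ArithmeticError):
    """Numerical overflow or non-finite intermediate during an equilibrium calculation."""


class NormalizationError(BindgateError, ValueError):
    """A competition curve cannot be normalized (zero bound label at zero competitor)."""


class NotCrossedError(BindgateError, ValueError):
    """A curve never crosses the half-signal level within its grid."""


class ConvergenceError(BindgateError, RuntimeError):
    """An iterative solver or fit failed to converge."""


class IdentifiabilityError(BindgateError, RuntimeError):
    """A fit is singular or its parameters are unidentifiable from the data."""


class DesignError(BindgateError, ValueError):
    """An invalid synthetic-data design (e.g. overlapping planted indels)."""
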