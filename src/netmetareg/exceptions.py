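"""Exception hierarchy.

Validation/schema problems are user-fixable input errors; estimability,
convergence and numerical errors signal that the requested model cannot be
fitted to the supplied evidence structure.
"""


class NetmetaregError(Exception):
    """Base class for all package errors."""


class SchemaError(NetmetaregError, ValueError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(NetmetaregError, ValueError):
    """Input values violate an invariant (e.g. events > total)."""


class DegenerateCellError(ValidationError):
    """A 2x2 cell count of zero with no continuity correction requested."""


class EstimabilityError(NetmetaregError, ValueError):
    """The design matrix is rank deficient; a parameter is not estimable."""


class ConvergenceError(NetmetaregError, RuntimeError):
    """An iterative estimation procedure failed to converge."""


class NumericalError(NetmetaregError, RuntimeError):
    """A matrix factorisation or similar numerical step failed."""


class UnsupportedConfigurationError(NetmetaregError, ValueError):
    """The requested operation is undefined for this model configuration."""
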