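"""Exception hierarchy shared across the package."""


class NephroHMMError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NephroHMMError, ValueError):
    """An argument violates a precondition (negative rate, bad threshold, ...)."""


class SchemaError(NephroHMMError):
    """A required column is missing or mistyped in an input table."""


class IntegrityError(NephroHMMError):
    """Input rows violate a structural invariant (duplicates, non-monotone times, unmatched keys)."""


class NoSolutionError(NephroHMMError):
    """A root-finding problem has no solution in the admissible domain."""


class InsufficientDataError(NephroHMMError):
    """Too few eligible observations or participants for estimation."""


class DegenerateDataError(NephroHMMError):
    """Data carry no information for the requested fit (e.g. all values identical)."""


class EstimationError(NephroHMMError):
    """A model fit is inestimable (no events, constant covariate, separation, rank deficiency)."""
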