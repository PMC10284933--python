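"""Exception hierarchy for stabkin."""


class StabilityError(Exception):
    """Base class for all stabkin errors."""


class DomainError(StabilityError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SchemaError(StabilityError, ValueError):
    """Malformed input file or table (missing columns, unparseable rows)."""


class ProfileError(StabilityError, ValueError):
    """Invalid temperature profile or query outside its domain."""


class DesignError(StabilityError):
    """Study design fails the good-modeling-practice rules."""


class ConvergenceError(StabilityError):
    """Nonlinear fit or bootstrap failed to converge."""


class IdentifiabilityError(StabilityError):
    """Requested fit is not identifiable from the supplied data."""


class IntegrationError(StabilityError):
    """ODE solver failed; carries solver diagnostics."""
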