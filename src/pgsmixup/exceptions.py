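"""Exception hierarchy shared across the package."""


class PgsMixupError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PgsMixupError):
    """Input data violates a structural contract (duplicate IDs, missing
    columns, undeclared ordinal categories, ...)."""


class FitError(PgsMixupError):
    """A regression or likelihood model could not be fitted."""


class ComputationError(PgsMixupError):
    """A downstream numeric computation produced an invalid value."""
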