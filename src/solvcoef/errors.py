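"""Exception hierarchy shared across the package."""


class SolvcoefError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SolvcoefError, ValueError):
    """An input value violates a precondition (non-finite field, bad range, ...)."""


class ConventionError(SolvcoefError, ValueError):
    """An operation requiring the zero-intercept convention received an
    original-convention row (or vice versa)."""


class DegeneratePopulationError(SolvcoefError, ValueError):
    """The solute population's [E S A B V] design matrix is rank deficient."""


class InsufficientDataError(SolvcoefError, ValueError):
    """Fewer rows than the operation can meaningfully work with."""


class SchemaError(SolvcoefError, KeyError):
    """A required column/feature is missing or a file header is malformed."""


class ModelFormatError(SolvcoefError, ValueError):
    """A serialized model artifact is corrupt or has an incompatible version."""
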