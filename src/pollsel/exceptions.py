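"""Exception hierarchy for pollsel."""


class PollselError(Exception):
    """Base class for all pollsel errors."""


class ConfigurationError(PollselError):
    """A model or run configuration is invalid."""


class ValidationError(PollselError):
    """Input data failed validation."""


class SchemaError(ValidationError):
    """A required column is missing or mistyped."""


class AlignmentError(ValidationError):
    """Two tables that must share plant ids do not."""


class DegenerateDataError(PollselError):
    """Data degenerate for the requested computation (retryable in bootstrap)."""


class DegenerateTraitError(DegenerateDataError):
    """A trait column has zero sample variance."""


class DegenerateFitnessError(DegenerateDataError):
    """A fitness vector is all zero (species received no seeds anywhere)."""


class NumericalError(PollselError):
    """A regression design is singular or rank deficient."""


class BootstrapRetryError(PollselError):
    """Bootstrap replicate redraw cap exceeded."""
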