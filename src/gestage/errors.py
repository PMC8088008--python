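"""Exception hierarchy shared across the package."""


class GestageError(Exception):
    """Base class for package errors."""


class SchemaError(GestageError):
    """A required column is missing or the schema config is malformed."""


class ValidationError(GestageError):
    """Input data violates a hard invariant."""


class DomainError(GestageError, ValueError):
    """A numeric argument is outside the mathematically valid domain."""


class ConfigError(GestageError):
    """A configuration object is inconsistent or references missing fields."""


class FormulaLookupError(GestageError, KeyError):
    """Requested formula id is not in the registry."""


class DuplicateFormulaError(GestageError):
    """Attempt to register a formula id that already exists."""


class PipelineError(GestageError):
    """A pipeline stage produced an unusable intermediate (e.g. empty data)."""


class OutOfRangeWarning(UserWarning):
    """Evaluation outside a formula's validated CRL range (still computed)."""
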