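"""Exception hierarchy shared across the pipeline."""


class BioageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BioageError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(BioageError, ValueError):
    """A required column is missing from a cohort table."""


class DegenerateDataError(BioageError, ValueError):
    """Data that makes an operation undefined (zero variance, no usable components)."""


class EmptyRiskSetError(BioageError, ValueError):
    """A survival analysis was requested on a risk set with no rows or no events."""


class NotNestedError(BioageError, ValueError):
    """A likelihood-ratio comparison between non-nested models."""


class OrderingError(BioageError, ValueError):
    """Nested-model log-likelihood ordering violated beyond numerical slack."""
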