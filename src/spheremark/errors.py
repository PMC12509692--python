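"""Exception hierarchy shared across the pipeline."""


class SpheremarkError(Exception):
    """Base class for all package errors."""


class ValidationError(SpheremarkError):
    """Input data violates a structural contract (duplicates, mismatches, ...)."""


class ConfigurationError(SpheremarkError):
    """A parameter value is outside its admissible range."""


class FormatError(SpheremarkError):
    """A file does not conform to its declared on-disk format."""


class StateError(SpheremarkError):
    """An operation was applied to data in the wrong state (e.g. wrong scale)."""
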