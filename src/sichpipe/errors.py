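"""Exception hierarchy shared across the pipeline stages."""


class SichPipeError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(SichPipeError):
    """A tabular input does not match the documented column schema."""


class ValidationError(SichPipeError):
    """A value violates a domain invariant (range, sign, uniqueness)."""


class DomainError(SichPipeError):
    """An operation was called outside its mathematical domain."""


class NoLesionError(DomainError):
    """A lesion mask required by an operation is empty."""


class NoBrainError(DomainError):
    """Brain extraction found no tissue component."""


class ConfigError(SichPipeError):
    """A required configuration entry (control class, threshold) is missing."""


class GeometryError(SichPipeError):
    """A gate polygon or other geometric input is degenerate."""


class SpecError(SichPipeError):
    """A synthetic-data specification is internally inconsistent."""
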