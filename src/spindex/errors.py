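"""Exception hierarchy for the spatial price index pipeline."""


class SpindexError(Exception):
    """Base class for all package errors."""


class SchemaError(SpindexError):
    """An input table is missing required columns or is otherwise malformed."""


class ValidationError(SpindexError):
    """Input data violates a domain invariant (duplicates, bad headings, ...)."""


class ComputationError(SpindexError):
    """A numerical precondition failed (non-positive price, rank deficiency, ...)."""
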