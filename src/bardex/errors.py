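"""Exception hierarchy shared across the pipeline stages."""


class BardexError(Exception):
    """Base class for all package errors."""


class SchemaError(BardexError):
    """An input table is missing a required column or has the wrong shape."""


class ValidationError(BardexError):
    """A value violates a domain invariant (named in the message)."""


class DegenerateROCError(BardexError):
    """ROC analysis was requested on single-class labels."""
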