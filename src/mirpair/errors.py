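"""Exception hierarchy.

Validation errors carry enough context to name the offending sample,
feature or pair; the CLI maps them onto distinct exit codes.
"""


class MirpairError(Exception):
    """Base class for all package errors."""


class ValidationError(MirpairError, ValueError):
    """Malformed or inconsistent input (bad labels, dimension mismatch...)."""


class SchemaMismatchError(ValidationError):
    """Input does not cover the pair-feature schema a trained model expects."""
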