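"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers malformed or contract-violating inputs and maps to
CLI exit code 1; any other ``SporevarError`` (or unexpected exception) maps to
exit code 2.
"""


class SporevarError(Exception):
    """Base class for all package errors."""


class ValidationError(SporevarError):
    """Input data violates a documented contract (bad label, ragged table...)."""


class FormatError(ValidationError):
    """A file does not have the expected columns or layout."""
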