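"""Exception hierarchy: parse failures vs validation failures.

The CLI maps these onto distinct exit codes (2 for parse errors, 3 for
validation errors).
"""


class MitocompError(Exception):
    """Base class for all package errors."""


class ParseError(MitocompError):
    """Raised when an input file cannot be read or decoded."""


class ValidationError(MitocompError):
    """Raised when parsed or constructed data violates a domain invariant."""
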