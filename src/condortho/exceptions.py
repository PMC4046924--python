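"""Exception hierarchy.

``ParseError`` marks malformed on-disk input (wrong column count,
non-numeric fields); ``ValidationError`` marks well-formed input that
violates a documented contract (negative counts, duplicate identifiers,
out-of-range parameters). The CLI maps these onto distinct exit codes.
"""


class CondorthoError(Exception):
    """Base class for all package errors."""


class ParseError(CondorthoError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(CondorthoError, ValueError):
    """Input parsed but violates an invariant or parameter contract."""
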