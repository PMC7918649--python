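"""Exception hierarchy.

``ValidationError`` marks bad inputs or configuration (CLI exit code 2);
any other :class:`CryogillError` is a runtime failure (exit code 1).
"""


class CryogillError(Exception):
    """Base class for all package errors."""


class ValidationError(CryogillError):
    """Invalid input data, file format, or parameter value."""
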