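"""Exception hierarchy.

``InputError`` marks problems with user-supplied data or configuration
(CLI exit code 1); any other exception is an internal error (exit 2).
"""


class RmorfError(Exception):
    """Base class for package errors."""


class InputError(RmorfError):
    """Malformed or inconsistent input data or configuration."""
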