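"""Exception hierarchy.

``ValidationError`` covers bad parameters or malformed inputs detected
before any computation; ``ComputationError`` covers failures arising
during a computation (degenerate data, empty results). The CLI maps the
two onto distinct exit codes.
"""


class FconnError(Exception):
    """Base class for all package errors."""


class ValidationError(FconnError, ValueError):
    """Invalid parameter or malformed input file."""


class ComputationError(FconnError, RuntimeError):
    """A computation could not be completed on the given data."""
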