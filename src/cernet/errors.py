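"""Exception hierarchy.

``UserError`` (and subclasses) signal bad inputs or bad invocations and map
to exit code 1 at the command line; anything else is an internal error
(exit code 2).
"""


class CernetError(Exception):
    """Base class for all package errors."""


class UserError(CernetError):
    """Invalid input data, configuration, or usage."""


class ValidationError(UserError):
    """A domain-type invariant was violated; the message names the offender."""


class ParseError(UserError):
    """A file could not be parsed; the message carries coordinates."""
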