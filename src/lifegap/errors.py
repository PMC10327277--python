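"""Exception hierarchy.

``ValidationError`` covers malformed user input (bad files, inconsistent
datasets, unparseable codes); anything else raised by the library is a
plain bug or a genuine runtime failure.  The CLI maps ``ValidationError``
to exit code 1 and other exceptions to exit code 2.
"""


class LifegapError(Exception):
    """Base class for all errors raised by lifegap."""


class ValidationError(LifegapError):
    """Input data or configuration violates a documented precondition."""


class FormatError(ValidationError):
    """A file does not follow the expected layout (e.g. an unsupported
    WHO age-format code)."""
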