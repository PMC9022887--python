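"""Exception hierarchy.

Exit-code mapping used by the CLI: input/format problems -> 2,
numerical failures -> 3.
"""


class CytonetError(Exception):
    """Base class for all package errors."""


class InputFormatError(CytonetError):
    """A file or table violates the expected format; message names the location."""


class InvalidParameterError(CytonetError, ValueError):
    """A parameter violates a precondition."""


class NumericalError(CytonetError):
    """An eigensolver or similar numerical routine failed."""
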