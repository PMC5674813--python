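"""Exception hierarchy.

Exit-code mapping in the CLI distinguishes parse (2), parameter (3) and
numerical (4) failures; library callers catch the classes directly.
"""


class OlnetError(Exception):
    """Base class for all package errors."""


class ParseError(OlnetError):
    """Malformed on-disk input (ragged rows, duplicate ids, non-numeric cells)."""


class ParameterError(OlnetError, ValueError):
    """Invalid argument values or inconsistent sizes."""


class InsufficientDataError(ParameterError):
    """Too few samples/features for the requested statistic."""


class NumericalError(OlnetError):
    """Undefined or degenerate numerical result (e.g. constant connectivity)."""
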