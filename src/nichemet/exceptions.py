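"""Typed errors raised by nichemet.

Every malformed input path raises one of these instead of propagating a
silent NaN; tests rely on the distinction between format problems (the file
cannot be interpreted at all) and validation problems (the file parses but
violates a data-model invariant).
"""


class NicheMetError(Exception):
    """Base class for all package errors."""


class FormatError(NicheMetError, ValueError):
    """A file or table does not have the expected layout (missing columns,
    wrong delimiter, unparsable cells)."""


class ValidationError(NicheMetError, ValueError):
    """The input parses but violates a data-model invariant (duplicate
    coordinates, negative intensities, unknown group labels, ...)."""


class DegenerateDataError(NicheMetError, ValueError):
    """A statistic is undefined on the given data (zero variance, empty
    support, constant anchor, single group, ...)."""
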