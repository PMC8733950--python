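"""Exception hierarchy.

Every error the library raises on invalid user input derives from
:class:`CladeDivError`, so callers (and the CLI) can distinguish bad input
from genuine bugs with a single ``except`` clause.
"""


class CladeDivError(Exception):
    """Base class for all cladediv input/validation errors."""


class NewickParseError(CladeDivError):
    """Malformed Newick text; carries a character/line position when known."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        if line is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)


class TreeValidationError(CladeDivError):
    """Structural problem in a parsed tree (duplicate leaves, missing lengths)."""


class UnknownLeafError(CladeDivError):
    """A requested leaf name does not exist in the tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"unknown leaf name(s): {', '.join(self.missing)}")


class CladeSelectionError(CladeDivError):
    """Clade designation is invalid (too small, nested, overlapping...)."""


class SpeciesError(CladeDivError):
    """Species-pattern extraction failed under the ``error`` policy."""


class SampleSizeError(CladeDivError):
    """A branch-length sample is too small for any two-sample test."""


class DegenerateSampleError(CladeDivError):
    """Samples have no usable variance for the requested test."""
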