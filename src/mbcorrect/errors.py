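"""Typed exceptions shared across the package.

Every failure mode a caller may reasonably want to catch gets its own
class; all inherit from :class:`MBCError` so ``except MBCError`` catches
anything raised deliberately by this package.
"""


class MBCError(Exception):
    """Base class for all errors raised by mbcorrect."""


class InvalidResidueError(MBCError):
    """A residue symbol is not one of the 20 canonical amino acids."""


class NotFoundError(MBCError):
    """A named resource (scale, registry entry) does not exist."""


class FormatError(MBCError):
    """A file does not conform to the expected dialect or schema."""


class RecordError(MBCError):
    """One or more rows of a mutation table failed validation.

    ``rows`` carries (row_index, reason) pairs when available.
    """

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class DuplicateKeyError(MBCError):
    """Duplicate mutation keys inside a single dataset where uniqueness is required."""


class IncompleteRecordError(MBCError):
    """Records lack fields required by the requested model mode."""

    def __init__(self, message: str, record_ids: list | None = None):
        super().__init__(message)
        self.record_ids = record_ids or []


class SingularSystemError(MBCError):
    """The normal equations are singular (rank-deficient design with lambda = 0)."""


class EmptyInputError(MBCError):
    """An operation received an empty dataset or empty value lists."""


class DegenerateInputError(MBCError):
    """A statistic is undefined on the input (e.g. zero variance for Pearson r)."""


class ShapeError(MBCError):
    """Paired inputs have mismatched lengths or misaligned keys."""
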