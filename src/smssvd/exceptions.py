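"""Exception hierarchy for smssvd.

All library-specific failures derive from :class:`SMSSVDError` so callers
(notably the CLI) can distinguish data/model errors from programming errors.
"""


class SMSSVDError(Exception):
    """Base class for all smssvd errors."""


class ShapeError(SMSSVDError):
    """Operands have incompatible shapes."""


class DimensionError(SMSSVDError):
    """A requested dimension is out of the admissible range."""


class RankError(SMSSVDError):
    """A matrix does not have the rank required by an operation.

    Raised e.g. when a subspace intersects the null space of the data
    matrix, or when a selected submatrix has rank below the requested
    truncation dimension.
    """


class EmptySelectionError(SMSSVDError):
    """A variable selection retained no variables."""


class CapacityError(SMSSVDError):
    """The orthogonal complement needed to draw a new direction is exhausted."""


class OrthogonalityError(SMSSVDError):
    """Factors that were supposed to be mutually orthogonal are not."""


class DataError(SMSSVDError):
    """Input data could not be parsed or violates basic integrity rules."""
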