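"""Exception hierarchy for flavopt.

Exit-code mapping for the CLI lives in :mod:`flavopt.cli`; library code raises
these and never calls ``sys.exit``.
"""


class FlavoptError(Exception):
    """Base class for all package errors."""


class ParseError(FlavoptError):
    """A delimited-text input could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description.
    row:
        Zero-based data-row index of the offending record, when known.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class UnsupportedDesignError(FlavoptError):
    """Requested experimental design is outside the supported family."""


class DegenerateFactorError(FlavoptError):
    """A factor has zero width (high == low), so coding is undefined."""


class SingularDesignError(FlavoptError):
    """The model matrix is rank deficient; carries the aliased column names."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(aliased)
        )


class ShapeError(FlavoptError):
    """Array dimensions are mutually inconsistent."""


class DegenerateRangeError(FlavoptError):
    """Normalization bounds collapse (xmax == xmin)."""


class TrainingDivergenceError(FlavoptError):
    """Network training produced a non-finite loss."""


class TransformDomainError(FlavoptError):
    """Kinetic log-transform undefined (concentration >= equilibrium)."""


class InvalidBoundsError(FlavoptError):
    """An optimization box is empty or malformed."""
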