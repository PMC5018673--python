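"""Exception hierarchy shared across the package."""


class AmaztraitsError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(AmaztraitsError):
    """Malformed Newick input; carries the character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class TreeValidationError(AmaztraitsError):
    """A tree violates a structural invariant (labels, branch lengths, shape)."""


class SchemaError(AmaztraitsError):
    """A delimited input file is missing mandatory columns."""


class TableParseError(AmaztraitsError):
    """A trait-table cell could not be interpreted; carries the row number."""


class InsufficientDataError(AmaztraitsError):
    """Fewer than the minimum number of matched tips/observations."""


class NumericalError(AmaztraitsError):
    """A linear-algebra step failed beyond the jitter policy."""


class ZeroBranchError(AmaztraitsError):
    """A contrast would divide by a zero combined branch length (strict mode)."""


class DegenerateGroupError(AmaztraitsError):
    """A grouped analysis received a group with too few observations."""


class LabelError(AmaztraitsError):
    """A report referenced a node id that does not exist in the scan."""
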