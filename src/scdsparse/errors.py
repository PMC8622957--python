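"""Exception hierarchy.

All scdsparse errors derive from :class:`ScdSparseError` so callers can catch
the whole family; most also derive from the closest builtin (ValueError for
bad arguments, RuntimeError for numerical failures) so idiomatic handling
still works.
"""


class ScdSparseError(Exception):
    """Base class for all scdsparse errors."""


class InvalidArgumentError(ScdSparseError, ValueError):
    """An argument violates a documented precondition."""


class DimensionMismatchError(InvalidArgumentError):
    """Array shapes are inconsistent (signal length vs dictionary rows, ...)."""


class RankDeficiencyError(ScdSparseError, RuntimeError):
    """The restricted least-squares system over a support set is singular."""

    def __init__(self, support, message=None):
        self.support = list(support)
        super().__init__(message or f"restricted system is rank-deficient on support {self.support}")


class InsufficientBeatsError(ScdSparseError, RuntimeError):
    """Fewer than two R peaks were found in a segment."""


class BoundaryError(ScdSparseError, ValueError):
    """A requested interval window falls outside the recording."""


class FormatError(ScdSparseError, ValueError):
    """A file could not be parsed in the documented dialect."""


class ValidationError(ScdSparseError, ValueError):
    """A parsed object violates a structural invariant."""


class SplitInfeasibleError(ScdSparseError, ValueError):
    """A class has too few subjects for the requested cross-validation split."""


class UnsupportedUpsamplingError(InvalidArgumentError):
    """Requested output rate exceeds the recording's native rate."""
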