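"""Exception hierarchy used across the package."""


class PpikitError(Exception):
    """Base class for all errors raised by ppikit."""


class InvalidArgumentError(PpikitError, ValueError):
    """An argument violates a documented precondition (shape, range, type)."""


class DegenerateInputError(PpikitError, ValueError):
    """Input is numerically degenerate (e.g. all-zero matrix, zero variance)."""


class RankDeficiencyError(PpikitError, ValueError):
    """A design matrix is rank deficient; the message names collinear columns."""


class BoundedSearchError(PpikitError, RuntimeError):
    """An iterative search hit its bound without satisfying its goal."""
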