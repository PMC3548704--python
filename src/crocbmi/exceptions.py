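"""Exception hierarchy.

Every error raised by the library derives from :class:`CrocBmiError` so that
callers (and the CLI) can distinguish domain errors from programming bugs.
"""


class CrocBmiError(Exception):
    """Base class for all crocbmi errors."""


class FormatError(CrocBmiError):
    """Malformed input file: ragged rows, duplicate ids, non-numeric cells."""


class CoverageError(CrocBmiError):
    """Gold-solution labels do not cover exactly the matrix's items."""


class DimensionError(CrocBmiError):
    """Vector length or matrix shape mismatch."""


class DegenerateInputError(CrocBmiError):
    """Input on which the requested statistic is undefined (constant vector)."""


class InsufficientFeaturesError(CrocBmiError):
    """Too few features for a reliable estimate (mutual-information distance)."""


class ParameterError(CrocBmiError):
    """Out-of-range or inconsistent parameter value."""


class DegenerateMatrixError(CrocBmiError):
    """Distance matrix that cannot be normalized (all off-diagonal zeros)."""


class UndefinedRateError(CrocBmiError):
    """TPR/FPR undefined: gold has a single class or only singletons."""


class UndefinedIndexError(CrocBmiError):
    """External index undefined for this pair of partitions."""


class UndefinedCorrelationError(CrocBmiError):
    """Too few valid points, or a constant series, for a Pearson correlation."""
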