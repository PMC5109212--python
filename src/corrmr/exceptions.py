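"""Exception hierarchy for the corrmr package.

All package-specific failures derive from :class:`CorrMrError`, so callers
(including the CLI) can distinguish analysis problems from programming bugs.
"""


class CorrMrError(Exception):
    """Base class for all corrmr errors."""


class FormatError(CorrMrError):
    """A text input does not conform to the expected tabular layout."""


class DuplicateRecordError(FormatError):
    """The same rsid appears more than once in one association table."""


class LdRangeError(FormatError):
    """A correlation entry lies outside [-1, 1] or the diagonal is not 1."""


class EmptyInstrumentError(CorrMrError):
    """No variant survives the genome-wide significance filter."""


class MissingCorrelationError(CorrMrError):
    """An instrument has no row/column in the supplied LD matrix."""


class AnnotationGapError(CorrMrError):
    """An instrument lacks a pleiotropy/function annotation."""


class AlleleMismatchError(CorrMrError):
    """Exposure and outcome alleles cannot be reconciled for one SNP."""


class WeakInstrumentError(CorrMrError):
    """A Wald ratio was requested for an instrument with zero exposure effect."""


class SingularWeightMatrixError(CorrMrError):
    """The outcome covariance (weight) matrix is not positive definite."""


class ScaleError(CorrMrError):
    """An estimate is on the wrong scale for the requested transformation."""


class DomainError(CorrMrError):
    """Numeric inputs violate a documented precondition (e.g. CI ordering)."""
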