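"""Exception hierarchy for subpert.

All package-specific failures derive from :class:`SubpertError` so callers
can catch one base class; format problems additionally derive from
``ValueError`` to behave like the standard library's parsing errors.
"""


class SubpertError(Exception):
    """Base class for all subpert errors."""


class PathwayFormatError(SubpertError, ValueError):
    """Malformed pathway interaction file."""


class ExpressionFormatError(SubpertError, ValueError):
    """Malformed expression-matrix file (GCT/TSV) or invalid values."""


class PhenotypeFormatError(SubpertError, ValueError):
    """Malformed phenotype-label file (CLS/TSV)."""


class EmptyPathwayError(SubpertError):
    """A pathway has no usable interactions (possibly after restriction)."""


class InsufficientSamplesError(SubpertError):
    """Fewer than two samples available in a group for a t statistic."""


class MissingScoreError(SubpertError, KeyError):
    """A gene required by a score computation has no differential-expression
    entry; callers should restrict the pathway to measured genes first."""


class ConfigurationError(SubpertError, ValueError):
    """Invalid user-supplied configuration (labels, universe, sizes)."""


class BruteForceCapError(SubpertError):
    """Exhaustive subgraph enumeration refused: too many interactions."""
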