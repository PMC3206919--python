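"""Exception hierarchy shared across the package."""


class MitopartError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(MitopartError):
    """Ragged rows, duplicate taxon labels, or unreadable alignment input."""


class AnnotationError(MitopartError):
    """Gene annotation indices outside the alignment, or malformed tables."""


class PartitionError(MitopartError):
    """Invalid partitioning request (e.g. codon blocks of a non-coding gene)."""


class ConcatenationError(MitopartError):
    """Taxon sets of the parts being concatenated do not match."""


class DistanceError(MitopartError):
    """Undefined pairwise distance (no comparable sites) or bad matrix input."""


class TreeComparisonError(MitopartError):
    """Leaf-set mismatch between trees being compared."""


class EnsembleError(MitopartError):
    """Inconsistent or empty posterior tree ensembles."""


class TraceError(MitopartError):
    """Malformed MCMC trace logs."""


class FitError(MitopartError):
    """Substitution-model fitting failed to converge or produced non-finite values."""


class ValidationError(MitopartError):
    """Gene-subset validation received incomplete clade support."""
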