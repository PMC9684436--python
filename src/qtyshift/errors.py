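"""Exception hierarchy.

Everything raised on bad user input derives from :class:`QtyShiftError`,
which itself derives from ``ValueError`` so callers that do not care about
the fine-grained class can still catch it conventionally.
"""


class QtyShiftError(ValueError):
    """Base class for all qtyshift errors."""


class ParameterError(QtyShiftError):
    """A numeric or structural parameter is out of its admissible range."""


class AlphabetError(QtyShiftError):
    """A sequence contains a letter outside the amino-acid alphabet."""


class AnnotationError(QtyShiftError):
    """A transmembrane interval is malformed or out of sequence bounds."""


class ComparisonError(QtyShiftError):
    """Two sequences that must be compared position-wise differ in length."""


class ChainSelectionError(QtyShiftError):
    """The requested chain does not exist in the coordinate file."""


class EmptyModelError(QtyShiftError):
    """A structure yields zero usable CA atoms."""


class MappingError(QtyShiftError):
    """Sequence-to-structure mapping failed or covers too little sequence."""


class UnderdeterminedError(QtyShiftError):
    """Fewer than three point pairs: the rigid superposition is underdetermined."""


class RefinementCollapseError(QtyShiftError):
    """Iterative outlier rejection discarded every residue pair."""


class PrecisionError(QtyShiftError):
    """Requested quadrature is too coarse to be meaningful."""


class LookupError_(QtyShiftError):
    """A remote accession could not be resolved (no cache hit, no network)."""
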