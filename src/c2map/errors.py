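"""Exception types shared across the package."""


class C2MapError(Exception):
    """Base class for all package errors."""


class StructureFormatError(C2MapError):
    """A coordinate file could not be parsed under the requested dialect."""


class EmptyStructureError(C2MapError):
    """A parsed file contained no polymer residues."""


class RangeError(C2MapError):
    """A residue range does not intersect the requested chain."""


class AnnotationError(C2MapError):
    """A C2 candidate could not be annotated (e.g. a strand with no H-bonds)."""


class AlignmentError(C2MapError):
    """Two domains cannot be aligned (e.g. mismatched topologies)."""


class DegeneracyError(C2MapError):
    """A numerical operation received degenerate input (collinear points, n < 3)."""


class StitchError(C2MapError):
    """Fragments cannot be stitched (insufficient or missing overlap)."""


class SpecError(C2MapError):
    """A synthetic-structure specification is geometrically infeasible."""
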