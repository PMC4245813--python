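"""Exception hierarchy for input validation and numerical failures."""


class PouTrajectoryError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(PouTrajectoryError):
    """Ragged alignment rows or other alignment-shape violations."""


class IdentifierError(PouTrajectoryError):
    """Duplicate or missing sequence/leaf identifiers."""


class AlphabetError(PouTrajectoryError):
    """Characters outside the amino-acid alphabet (plus '-' and 'X')."""


class NewickParseError(PouTrajectoryError):
    """Malformed Newick input."""


class AnnotationError(PouTrajectoryError):
    """Overlapping or otherwise inconsistent structural annotation."""


class RangeError(PouTrajectoryError):
    """Annotation column outside the alignment's column space."""


class InputError(PouTrajectoryError):
    """Cross-reference failure between alignment, trees and maps."""


class DegenerateProfileError(PouTrajectoryError):
    """A site profile with zero variance cannot support a correlation test."""
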