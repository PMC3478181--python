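"""Exception hierarchy.

Every error the library raises derives from :class:`CoevomutError`, so
callers (and the CLI) can catch one base class.
"""


class CoevomutError(Exception):
    """Base class for all coevomut errors."""


class AlignmentFormatError(CoevomutError):
    """Rows of unequal length, unparseable file, or illegal characters."""


class EmptyInputError(CoevomutError):
    """An input that must be non-empty was empty."""


class DuplicateIdError(CoevomutError):
    """Two sequences in one alignment share an identifier."""


class EmptyQueryError(CoevomutError):
    """The query row consists entirely of gaps."""


class TooFewSequencesError(CoevomutError):
    """Reduction would shrink the alignment below the allowed minimum."""


class EmptyAlignmentError(CoevomutError):
    """All columns were removed."""


class InsufficientDataError(CoevomutError):
    """Fewer than two usable rows for a column pair."""


class InvalidNError(CoevomutError):
    """The RCW normalisation count n is smaller than 2."""


class InvalidCodeError(CoevomutError):
    """A degenerate codon contains a non-IUPAC letter."""


class InvalidCodonError(CoevomutError):
    """A concrete codon is not a DNA triplet over ACGT."""


class FlankTooShortError(CoevomutError):
    """Target codon too close to a CDS end for the requested primer length."""


class FrameError(CoevomutError):
    """CDS length is not a multiple of three."""


class InsufficientSitesError(CoevomutError):
    """Fewer than two sites supplied for distance statistics."""


class MissingCoordinateError(CoevomutError):
    """A site lacks 3D coordinates."""


class IncompleteRecordError(CoevomutError):
    """A variant record is missing data for a designed site."""


class InconsistentRecordsError(CoevomutError):
    """Variant records do not share the same designed-site set."""


class ConfigError(CoevomutError):
    """Invalid simulation configuration."""
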