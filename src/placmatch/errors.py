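"""Exception hierarchy shared across the package."""


class PlacmatchError(Exception):
    """Base class for all package errors."""


class ParseError(PlacmatchError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(PlacmatchError):
    """Input columns or locus names do not match the expected schema."""


class ValidationError(PlacmatchError):
    """Input values violate a documented precondition or invariant."""


class EncodingError(PlacmatchError):
    """Allele labels cannot be represented in the requested output coding."""


class PedigreeError(PlacmatchError):
    """Pedigree structure is invalid (e.g. an individual is its own ancestor)."""


class SeparationError(PlacmatchError):
    """Logistic regression cannot be fitted: separated or degenerate outcome."""


class UndeterminedPairError(ValidationError):
    """A mare-foal pair has no testable locus in the requested MHC class."""
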