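"""Exception hierarchy shared across the package."""


class ConfmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ConfmapError, ValueError):
    """An input violates a documented precondition."""


class CoordinateError(ValidationError):
    """Peptide or residue coordinates fall outside the parent sequence."""


class FormatError(ConfmapError):
    """A file does not conform to the expected dialect."""


class GridMismatchError(ValidationError):
    """Two spectra are not sampled on the identical wavenumber grid."""


class DegenerateReferenceError(ValidationError):
    """The vapor reference carries no signal in the scaling window."""


class NormalizationError(ValidationError):
    """Spectrum area in the normalization window is zero or negative."""


class RankDeficiencyError(ConfmapError):
    """Candidate wavenumbers are collinear; no informative regressor exists."""


class UndefinedRFUError(ValidationError):
    """Relative fractional uptake is undefined (no exchangeable amides)."""


class InsufficientReplicatesError(ValidationError):
    """Statistical operation requires more replicates than provided."""


class EmptyComparisonError(ValidationError):
    """Two states share no peptide/exposure combination."""


class NonIdentifiableError(ConfmapError):
    """A model fit cannot be constrained by the data (e.g. flat titration)."""


class MappingError(ValidationError):
    """Structure residues cannot be matched to the residue profile."""
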