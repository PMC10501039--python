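"""Exception hierarchy shared across the package."""


class VocscreenError(Exception):
    """Base class for all package-specific errors."""


class PeakTableFormatError(VocscreenError):
    """Malformed peak/cohort table input (missing column, bad header)."""


class DuplicateRecordError(PeakTableFormatError):
    """The same (subject, voc, m/z) cell appears more than once."""


class EmptyTableError(PeakTableFormatError):
    """A table file contains a header but no data rows."""


class NoSignalError(VocscreenError):
    """Every fragment area of a species is zero; no quantifier ion exists."""


class RetentionRangeError(VocscreenError):
    """Retention time falls outside the calibrated n-alkane window."""


class InsufficientDataError(VocscreenError):
    """Too few (non-missing) observations for the requested analysis."""


class ConstantInputError(VocscreenError):
    """Correlation or regression requested on a constant variable."""


class SingularFitError(VocscreenError):
    """Rank-deficient design matrix or singular covariance."""


class DimensionError(VocscreenError):
    """Feature-vector length does not match the fitted model."""


class ConfigError(VocscreenError):
    """Invalid generator or pipeline configuration."""
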