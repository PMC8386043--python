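"""Exception hierarchy for ampliquant.

All package errors derive from :class:`AmpliquantError` so callers can catch a
single base class at pipeline level while tests distinguish specific failures.
"""


class AmpliquantError(Exception):
    """Base class for all ampliquant errors."""


class ValidationError(AmpliquantError):
    """A RunData or configuration object violates its invariants."""


class RdmlFormatError(AmpliquantError):
    """Input is not a readable RDML archive (e.g. not a zip file)."""


class RdmlStructureError(AmpliquantError):
    """The RDML XML document is missing a required element."""


class UnsupportedVersionError(AmpliquantError):
    """The RDML document declares a version below 1.1."""


class TableFormatError(AmpliquantError):
    """A flat instrument table is ragged or lacks required columns."""


class TableParseError(AmpliquantError):
    """A table cell could not be parsed; carries row/column position."""

    def __init__(self, message, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class AnalysisError(AmpliquantError):
    """Run- or assay-level analysis failure."""


class InsufficientDataError(AnalysisError):
    """Too few data points for the requested operation."""


class NoAmplificationError(AnalysisError):
    """No usable exponential phase could be identified in a reaction."""


class WindowInvalidError(AnalysisError):
    """A fitting window is too short or contains non-positive fluorescence."""


class UndefinedEfficiencyError(AnalysisError):
    """An operation requires a PCR efficiency strictly above 1."""


class AssayError(AnalysisError):
    """No window of linearity could be established for an assay."""


class NormalizationError(AmpliquantError):
    """Melting-curve normalization failed (degenerate anchor trends)."""


class QuantificationError(AmpliquantError):
    """Peak fluorescence quantification failed (zero total fluorescence)."""


class PlanError(AmpliquantError):
    """A synthetic plate plan is invalid (e.g. duplicate wells)."""
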