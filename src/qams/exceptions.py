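"""Exception and warning hierarchy.

All library errors derive from :class:`QAMSError`; most also derive from
``ValueError`` or ``KeyError`` so that generic callers behave sensibly.
"""


class QAMSError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(QAMSError, ValueError):
    """A quantity left its mathematical domain (e.g. log of a nonpositive area)."""


class InsufficientDataError(QAMSError, ValueError):
    """Too few observations for the requested statistic or fit."""


class DegenerateDesignError(QAMSError, ValueError):
    """The design carries no information (e.g. all concentrations identical)."""


class DegenerateCurveError(DegenerateDesignError):
    """A calibration curve cannot be inverted (zero slope)."""


class PairingError(QAMSError, ValueError):
    """Two series or sample sets that must be paired do not line up."""


class PanelLookupError(QAMSError, KeyError):
    """A referenced analyte, curve, or RCF entry is missing from the panel."""


class ConsistencyError(QAMSError, ValueError):
    """Inputs that must agree (method, marker) do not."""


class SchemaError(QAMSError, ValueError):
    """A delimited input table violates the expected schema."""


class DesignError(QAMSError, ValueError):
    """An invalid simulation design (e.g. duplicate dilution factors)."""


class CalibrationRangeWarning(UserWarning):
    """A predicted concentration lies outside the calibrated range."""


class LogDomainWarning(UserWarning):
    """An area in (0, 1) makes its base-10 log negative; formulas that divide
    by log-areas silently change sign there."""


class DegenerateLevelWarning(UserWarning):
    """A calibration level is degenerate for the requested formula
    (e.g. concentration exactly 1 makes lg C zero)."""
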