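"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`Glut4QuantError`
so callers can catch pipeline failures without masking programming errors.
"""


class Glut4QuantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(Glut4QuantError, ValueError):
    """A parameter violates its documented precondition."""


class CalibrationError(Glut4QuantError):
    """Missing or invalid pixel-size calibration."""


class FormatError(Glut4QuantError):
    """Image pages/channels are inconsistent (e.g. mismatched shapes)."""


class ChannelRoleError(Glut4QuantError):
    """A mandatory channel role (glut4, dystrophin) is absent."""


class ConfigValidationError(Glut4QuantError):
    """Configuration failed validation; carries the full violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration: " + "; ".join(self.violations))


class SegmentationError(Glut4QuantError):
    """Fibre segmentation failed (no object, unrepairable contour, ...)."""


class DegenerateFibreError(Glut4QuantError):
    """Fibre too small for the requested band/layer geometry."""


class InsufficientDataError(Glut4QuantError):
    """Not enough observations for the requested batch operation."""


class SpotPlacementError(Glut4QuantError):
    """Requested spot count could not be placed without overlap."""


class InvalidSpotError(Glut4QuantError, ValueError):
    """Non-positive spot area/diameter."""


class UndefinedStatisticError(Glut4QuantError):
    """A test statistic is undefined for the given data (n < 2, zero variance)."""


class IncompleteDesignError(Glut4QuantError):
    """ANOVA table has missing cells or unbalanced groups; no imputation is done."""


class AssignmentError(Glut4QuantError):
    """A spot centroid fell outside every analysed region."""


class QCThresholdError(Glut4QuantError):
    """Too large a fraction of images failed quality control."""
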