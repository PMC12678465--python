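"""Exception hierarchy.

Validation errors (bad user input) derive from :class:`ValidationError`;
degenerate-data conditions (structurally valid input on which the requested
statistic is undefined) derive from :class:`DegenerateDataError`.  The CLI
maps these to exit codes 2 and 3 respectively.
"""


class VentriculometryError(Exception):
    """Base class for all package errors."""


class ValidationError(VentriculometryError, ValueError):
    """Invalid input: bad measurement, config, profile name, file content."""


class DegenerateDataError(VentriculometryError, ValueError):
    """Structurally valid input on which the computation is undefined."""


# -- measurements -----------------------------------------------------------

class InvalidMeasurementError(ValidationError):
    """A linear measurement violates positivity/finiteness/ordering; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


# -- landmark geometry ------------------------------------------------------

class MissingAffineError(ValidationError):
    """Voxel-space landmark pair supplied without a voxel-to-world affine."""


class InvalidAffineError(ValidationError):
    """Affine is singular or not a proper homogeneous transform."""


class DuplicateLandmarkError(ValidationError):
    """The same landmark label appears more than once."""


class MissingLandmarkError(ValidationError):
    """Required landmark labels absent; carries the list of missing labels."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing landmark labels: {', '.join(self.missing)}")


# -- statistics -------------------------------------------------------------

class DegenerateLabelsError(DegenerateDataError):
    """ROC requested but only one class is present."""


class InvalidScoreError(ValidationError):
    """Non-finite score passed to the ROC routine."""


class UndefinedRateError(DegenerateDataError):
    """Confusion rate with an empty margin; names the undefined rate."""

    def __init__(self, rate: str):
        self.rate = rate
        super().__init__(f"{rate} undefined: empty margin")


class UnsupportedSizeError(ValidationError):
    """Sample size outside the supported range of a test."""


class DegenerateTableError(DegenerateDataError):
    """2x2 table with a zero margin."""


class CollinearityError(ValidationError):
    """Constant or collinear covariate in a regression design."""


class ConvergenceError(VentriculometryError):
    """Iterative fit failed to converge and separation was not detected."""


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation detected in a logistic fit."""


# -- cohort simulation ------------------------------------------------------

class ConfigValidationError(ValidationError):
    """Cohort config invalid; message lists every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid cohort config: " + "; ".join(self.violations))


class InfeasibleTargetError(ValidationError):
    """Target index panel cannot be realized under the measurement priors."""


# -- pipeline ---------------------------------------------------------------

class UnknownProfileError(ValidationError):
    """Cutoff profile name not recognised; lists the available profiles."""

    def __init__(self, name: str, available):
        self.available = sorted(available)
        super().__init__(
            f"unknown cutoff profile {name!r}; available: {', '.join(self.available)}"
        )


class IncompleteRecordError(ValidationError):
    """A subject record lacks the index values required for the analysis."""


class DegenerateCohortError(DegenerateDataError):
    """Cohort with a single diagnostic group cannot be analysed."""
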