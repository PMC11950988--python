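"""Exception hierarchy for the aspectscore pipeline.

Every stage raises a subclass of :class:`AspectscoreError` so batch drivers
can catch one type, attach the patient id and stage name, and continue.
"""


class AspectscoreError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(AspectscoreError):
    """Invalid configuration, specification or input data."""


class SizingError(ValidationError):
    """Image too small to place the requested geometry."""


class SkullStripError(AspectscoreError):
    """No closed skull ring could be found in the image."""


class RegistrationError(AspectscoreError):
    """Registration failed to converge or produced an implausible metric.

    Carries the final metric value in :attr:`metric`.
    """

    def __init__(self, message: str, metric: float | None = None):
        super().__init__(message)
        self.metric = metric


class SegmentationError(AspectscoreError):
    """A region mask was lost or emptied during transfer; names the region."""

    def __init__(self, message: str, region: str | None = None):
        super().__init__(message)
        self.region = region


class CalibrationError(AspectscoreError):
    """Calibration cohort unusable (e.g. single-class truth for a region)."""


class FormatError(AspectscoreError):
    """Unsupported or malformed input file format."""
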