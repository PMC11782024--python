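"""Exception hierarchy for the AVS analysis pipeline."""


class AVSKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(AVSKitError, ValueError):
    """A raw measurement violates the positivity/shape invariants."""


class CannotLabelError(AVSKitError):
    """Reference labeling requested without bilaterally successful indices."""


class DegenerateContrastError(AVSKitError, ValueError):
    """A binary contrast contains only one class."""


class InfeasibleConstraintError(AVSKitError):
    """No ROC operating point satisfies the minimum-specificity floor."""

    def __init__(self, min_specificity: float, max_attainable: float, contrast: str = ""):
        self.min_specificity = min_specificity
        self.max_attainable = max_attainable
        self.contrast = contrast
        where = f" for contrast {contrast!r}" if contrast else ""
        super().__init__(
            f"no operating point{where} attains specificity > {min_specificity:g} "
            f"(maximum attainable with nonzero sensitivity: {max_attainable:g})"
        )


class ThresholdOrderingError(AVSKitError):
    """Derived decision boundaries are not ordered right < bilateral <= left."""


class GenerationError(AVSKitError):
    """The synthetic cohort generator exhausted its redraw budget."""


class ValidationError(AVSKitError, ValueError):
    """Cohort file or configuration failed validation."""
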