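"""Exception hierarchy. Every pipeline stage raises a subclass of
:class:`MousemimeError` so callers can trap domain failures separately
from programming errors."""


class MousemimeError(Exception):
    """Base class for all pipeline errors."""


class InvalidLabelError(MousemimeError):
    """An emotional-state label outside {neutral, tail_pinch, brushing}."""


class RenderError(MousemimeError):
    """A facial part would fall (partly) outside the image frame."""


class DetectionError(MousemimeError):
    """No plausible subject found in a frame; the frame is excluded."""


class AlignmentError(MousemimeError):
    """Mask and image shapes disagree."""


class ConfigurationError(MousemimeError):
    """An invalid stage parameter (e.g. non-positive resize side)."""


class BalancingError(MousemimeError):
    """A class has no samples, so classes cannot be equalized."""


class SplitError(MousemimeError):
    """A class is too small to be split into train/validation/test."""


class ConstructionError(MousemimeError):
    """A malformed network specification."""


class TrainingError(MousemimeError):
    """Training diverged (non-finite loss). Carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class LayerLookupError(MousemimeError):
    """Requested Grad-CAM target layer does not exist in the model."""


class FitError(MousemimeError):
    """Ellipse fitting failed (empty or degenerate mask)."""


class UndefinedOrientationError(MousemimeError):
    """A circular fit (a == b) has no major-axis orientation."""


class GeometryError(MousemimeError):
    """Coincident landmark points make an angle undefined."""


class LabelError(MousemimeError):
    """A prediction or truth label outside the configured classes."""


class StageError(MousemimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
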