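"""Exception hierarchy for the secretomap pipeline.

Every stage raises a subclass of :class:`SecretomapError` so that the
orchestrator can attribute a failure to a stage without string matching.
"""


class SecretomapError(Exception):
    """Base class for all pipeline errors."""


class FormatError(SecretomapError):
    """Input file exists but is not an acceptable grayscale stack."""


class BoundsError(SecretomapError):
    """A requested window or ROI does not lie inside the frame."""


class ConfigurationError(SecretomapError):
    """Invalid or inconsistent configuration (e.g. missing reference well)."""


class AlignmentError(SecretomapError):
    """Paired stacks disagree in frame count or timing."""


class InsufficientFramesError(SecretomapError):
    """An operation needs more frames than the stack provides."""


class TrainingError(SecretomapError):
    """Pixel-classifier training cannot proceed (e.g. single-class labels)."""


class CompatibilityError(SecretomapError):
    """A trained model was applied with a mismatched feature bank."""


class DetectionError(SecretomapError):
    """No microwell circle found above the accumulator score threshold."""


class FitError(SecretomapError):
    """A linear segment fit was requested on too few samples."""
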