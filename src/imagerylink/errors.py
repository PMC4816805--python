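"""Exception hierarchy shared across the pipeline stages."""


class ValidationError(ValueError):
    """An input violates a documented precondition (range, shape, missing value)."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class GridMismatchError(ValidationError):
    """Volumes that must share a voxel grid do not."""


class EmptyMaskError(ValidationError):
    """A mask or ROI contains no voxels where at least one was required."""


class UnsupportedOrientationError(ValidationError):
    """A NIfTI affine is not axis-aligned with positive voxel sizes."""
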