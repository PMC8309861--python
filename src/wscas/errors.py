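"""Exception types shared across the pipeline stages."""


class WscasError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(WscasError):
    """Scene geometry is invalid (e.g. the crop/harvested boundary lies
    entirely outside the field band, leaving one class empty)."""


class NoRegionError(WscasError):
    """No admissible class-pure window exists for the requested class."""

    def __init__(self, class_id: int, message: str | None = None):
        self.class_id = class_id
        super().__init__(message or f"no admissible window for class {class_id}")


class EmptyMaskError(WscasError):
    """A segmentation mask contains no foreground pixels."""


class DegenerateContourError(WscasError):
    """The boundary's row extent is too small to survive trimming."""


class NoLineError(WscasError):
    """No Hough accumulator cell reached the vote threshold."""


class ModelError(WscasError):
    """Model construction or checkpoint mismatch."""


class BundleError(WscasError):
    """On-disk scene bundle is malformed (missing or mismatched files)."""
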