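"""Exception hierarchy shared across the package."""


class SonodaeError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SonodaeError, ValueError):
    """A parameter is outside its documented domain."""


class ShapeError(SonodaeError, ValueError):
    """Array dimensions do not chain."""


class DegenerateBipartitionError(SonodaeError):
    """The image cannot be split into two non-empty intensity classes."""


class DivergenceError(SonodaeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, stage: str = "training"):
        self.epoch = epoch
        self.stage = stage
        super().__init__(f"non-finite loss during {stage} at epoch {epoch}")


class InvalidLabelError(SonodaeError, ValueError):
    """A class label is outside {0, 1} / {benign, malignant}."""


class InvalidSpecError(SonodaeError, ValueError):
    """A phantom specification is internally inconsistent."""


class InvalidSplitError(SonodaeError, ValueError):
    """A dataset split leaves a class with too few samples."""
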