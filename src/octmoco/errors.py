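"""Exception hierarchy shared across the pipeline."""


class OctMocoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OctMocoError, ValueError):
    """A file or array does not match the declared protocol/shape."""


class NoSurfaceError(OctMocoError, RuntimeError):
    """Segmentation could not locate a sample surface in a B-scan."""


class MotionRangeError(OctMocoError, ValueError):
    """Estimated or injected motion exceeds the imaging range."""


class StageError(OctMocoError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
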