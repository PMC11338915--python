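"""Exception hierarchy.

All failures raised by this package derive from :class:`LungCTRError`, so
callers can catch one type at the CLI boundary.  ``PipelineError`` wraps a
stage failure with the name of the stage that raised it.
"""


class LungCTRError(Exception):
    """Base class for all package errors."""


class MaskInputError(LungCTRError):
    """Unreadable, empty, or otherwise invalid raster input."""


class ComponentError(LungCTRError):
    """Connected-component post-processing failed (e.g. merged lungs)."""


class ContourError(LungCTRError):
    """Boundary tracing or arc extraction failed."""


class LandmarkError(LungCTRError):
    """A landmark could not be located on the contour."""


class PipelineError(LungCTRError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
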