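"""Exception hierarchy.

Every stage raises a subclass of :class:`HistokurtError` so pipeline code can
abort with the stage name attached while library users can catch precisely.
"""


class HistokurtError(Exception):
    """Base class for all histokurt errors."""


class PlacementError(HistokurtError):
    """Nucleus placement failed after bounded retries."""


class InsufficientTissueError(HistokurtError):
    """Too few above-threshold optical-density pixels to estimate stains."""


class DegenerateStainError(HistokurtError):
    """OD point cloud is (near) rank-1 or the stain basis is collinear."""


class BlankChannelError(HistokurtError):
    """A concentration channel is identically zero where tissue is expected."""


class ConstantRegionError(HistokurtError):
    """Moment statistics are undefined on a constant-valued region."""


class SurvivalModelError(HistokurtError):
    """Cox / cutpoint / KM input is invalid or the fit cannot proceed."""


class PipelineStageError(HistokurtError):
    """A pipeline stage aborted; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
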