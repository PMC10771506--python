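"""Exception hierarchy shared across the pipeline stages."""


class ClotflowError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ClotflowError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class RenderingError(ClotflowError):
    """Synthetic scene cannot be rasterized (e.g. ellipse leaves the frame)."""


class SegmentationFailure(ClotflowError):
    """A single frame could not be segmented into a closed clot boundary."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class DegenerateClusteringError(ClotflowError):
    """Intensity clustering is undefined (all pixels identical)."""


class GeometryError(ClotflowError):
    """Boundary-geometry operation failed (open curve, center outside, ...)."""


class SolverError(ClotflowError):
    """Finite-element solve diverged or was handed inconsistent fields."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history


class PipelineError(ClotflowError):
    """Stage-level failure (too many bad frames, missing upstream artifact)."""


class DependencyError(PipelineError):
    """A requested stage is missing an upstream artifact."""

    def __init__(self, message: str, required_stage: str | None = None):
        super().__init__(message)
        self.required_stage = required_stage
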