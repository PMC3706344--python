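"""Exception types raised across the package."""


class SpectCVError(Exception):
    """Base class for all spectcv errors."""


class SizingError(SpectCVError):
    """Requested phantom does not fit the voxel grid."""


class PackingError(SpectCVError):
    """Lesion packing could not reach the requested occupancy."""

    def __init__(self, message: str, achieved_occupancy: float):
        super().__init__(message)
        self.achieved_occupancy = achieved_occupancy


class ConsistencyError(SpectCVError):
    """Inputs that must refer to the same phantom/grid do not."""


class ShapeError(SpectCVError):
    """Incompatible grid shapes or pitches."""


class NormalisationError(SpectCVError):
    """Projection data cannot be rescaled (e.g. all zero)."""


class SettingsError(SpectCVError):
    """Invalid reconstruction or analysis settings."""


class SegmentationError(SpectCVError):
    """Lung segmentation failed (empty or degenerate input)."""


class PeelError(SpectCVError):
    """Edge peeling removed the entire mask."""

    def __init__(self, message: str, emptied_at_layer: int):
        super().__init__(message)
        self.emptied_at_layer = emptied_at_layer


class AnalysisError(SpectCVError):
    """CV analysis cannot proceed (e.g. no valid CV values)."""


class PlanError(SpectCVError):
    """Invalid experiment plan."""


class DomainError(SpectCVError, ValueError):
    """Argument outside its mathematical domain."""
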