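"""Core in-memory containers: volumes, masks and projection sets.

All 3-D arrays use ``(z, y, x)`` index order with isotropic voxels; axis 0
runs from the lung apex (index 0) towards the base.  Physical coordinates
are in millimetres, ``coordinate = index * voxel_pitch_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError

__all__ = ["ActivityVolume", "LungMask", "AttenuationMap", "ProjectionSet"]


@dataclass
class ActivityVolume:
    """A 3-D scalar field of activity concentration on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Activity concentration per voxel, arbitrary units.
    voxel_pitch_mm : float
        Isotropic voxel edge length in mm.
    provenance : str
        ``"phantom"`` for ground-truth distributions, ``"reconstruction"``
        for tomographic estimates.
    """

    data: np.ndarray
    voxel_pitch_mm: float
    provenance: str = "phantom"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"activity volume must be 3-D, got {self.data.ndim}-D")
        if not self.voxel_pitch_mm > 0:
            raise ValueError("voxel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_pitch_mm / 10.0) ** 3

    def total_activity(self) -> float:
        return float(self.data.sum())


@dataclass
class LungMask:
    """Boolean lung field on the same grid as the volumes it is used with.

    ``variant`` distinguishes the full segmented lung from the edge-peeled
    analysis volume.
    """

    data: np.ndarray
    voxel_pitch_mm: float
    variant: str = "full"  # "full" | "peeled"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ShapeError(f"lung mask must be 3-D, got {self.data.ndim}-D")
        if not self.voxel_pitch_mm > 0:
            raise ValueError("voxel_pitch_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_L(self) -> float:
        """Physical mask volume in litres."""
        return self.voxel_count * (self.voxel_pitch_mm / 10.0) ** 3 / 1000.0


@dataclass
class AttenuationMap:
    """Linear attenuation coefficients (cm^-1) on the phantom grid."""

    data: np.ndarray
    voxel_pitch_mm: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError("attenuation map must be 3-D")
        if (self.data < 0).any():
            raise ValueError("attenuation coefficients must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ProjectionSet:
    """An ordered set of parallel-beam projections.

    ``images`` has shape ``(n_angles, nz, nx_det)``; each image holds mean
    counts (``kind="mean"``) or integer Poisson counts (``kind="counts"``).
    """

    angles_deg: np.ndarray
    images: np.ndarray
    pixel_pitch_mm: float
    kind: str = "mean"  # "mean" | "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3 or len(self.angles_deg) != self.images.shape[0]:
            raise ShapeError("images must be (n_angles, nz, nx) matching angles")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    def total_counts(self) -> float:
        return float(self.images.sum())
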