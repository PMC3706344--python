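"""Lung-volume definition and edge peeling.

Two segmentation rules are provided: the phantom rule (voxels above half
the maximum of a reconstruction of the uniform reference distribution)
and the CT rule (attenuation below an empirical threshold inside the body
envelope).  Because the SPECT system blurs the lung boundary, one or more
voxel layers are morphologically "peeled" off before CV analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import DomainError, PeelError, SegmentationError
from .volumes import ActivityVolume, AttenuationMap, LungMask

__all__ = [
    "SegmentationSettings",
    "PeeledMask",
    "lung_from_reconstruction",
    "lung_from_ct",
    "peel",
]

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegmentationSettings:
    mode: str = "phantom-halfmax"  # or "ct-threshold"
    ct_threshold_cm: float = 0.12
    peel_layers: int = 1

    def __post_init__(self):
        if self.mode not in ("phantom-halfmax", "ct-threshold"):
            raise DomainError("unknown segmentation mode")
        if not self.ct_threshold_cm > 0:
            raise DomainError("ct threshold must be positive")
        if self.peel_layers < 0:
            raise DomainError("peel layers must be >= 0")


class PeeledMask(NamedTuple):
    mask: LungMask
    removed_percent: float


def lung_from_reconstruction(recon_of_normal: ActivityVolume) -> LungMask:
    """Half-maximum lung definition from a uniform-reference reconstruction.

    The lung is the set of voxels with value strictly greater than half
    the global maximum.
    """
    peak = recon_of_normal.data.max()
    if peak <= 0:
        raise SegmentationError("cannot segment an all-zero reconstruction")
    mask = recon_of_normal.data > 0.5 * peak
    return LungMask(mask, recon_of_normal.voxel_pitch_mm, variant="full")


def lung_from_ct(
    attn: AttenuationMap,
    threshold_cm: float = 0.12,
    keep_components: int = 2,
    seed_points: np.ndarray | None = None,
) -> LungMask:
    """Threshold segmentation of the lung from an attenuation (CT) volume.

    Voxels with attenuation below ``threshold_cm`` are lung candidates;
    exterior air is removed by discarding low-attenuation connected
    components that touch the volume border, and the ``keep_components``
    largest remaining components are retained.  Optional ``seed_points``
    (voxel coordinates) override the size criterion and keep exactly the
    components containing the seeds.
    """
    if not threshold_cm > 0:
        raise DomainError("threshold must be positive")
    low = attn.data < threshold_cm
    labels, n = ndimage.label(low, structure=FACE_STRUCTURE)
    if n == 0:
        raise SegmentationError("no voxels below the attenuation threshold")
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    interior = np.setdiff1d(np.arange(1, n + 1), border_labels)
    if interior.size == 0:
        raise SegmentationError(
            "no interior low-attenuation component (body envelope not closed?)"
        )
    if seed_points is not None:
        pts = np.asarray(seed_points, dtype=int).reshape(-1, 3)
        chosen = np.unique(labels[pts[:, 0], pts[:, 1], pts[:, 2]])
        chosen = chosen[np.isin(chosen, interior)]
        if chosen.size == 0:
            raise SegmentationError("no seed point lies in an interior component")
    else:
        sizes = ndimage.sum_labels(low, labels, interior)
        chosen = interior[np.argsort(sizes)[::-1][:keep_components]]
    mask = np.isin(labels, chosen)
    return LungMask(mask, attn.voxel_pitch_mm, variant="full")


def peel(mask: LungMask, layers: int = 1) -> PeeledMask:
    """Erode ``layers`` one-voxel-wide boundary layers off the mask.

    Erosion uses the face-adjacent (6-connected) structuring element, so
    one layer removes exactly the voxels with an out-of-mask face
    neighbour.  Returns the peeled mask and the removed fraction as a
    percent of the input mask volume.
    """
    if layers < 0:
        raise DomainError("layers must be >= 0")
    n0 = mask.voxel_count
    if n0 == 0:
        raise SegmentationError("cannot peel an empty mask")
    data = mask.data
    for layer in range(1, layers + 1):
        data = ndimage.binary_erosion(data, structure=FACE_STRUCTURE)
        if not data.any():
            raise PeelError(
                f"mask emptied while peeling layer {layer} of {layers}",
                emptied_at_layer=layer,
            )
    removed = 100.0 * (n0 - data.sum()) / n0
    variant = "peeled" if layers > 0 else mask.variant
    return PeeledMask(LungMask(data, mask.voxel_pitch_mm, variant=variant), removed)
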