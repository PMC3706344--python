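"""Two-lung digital phantom and lesioned activity distributions.

The phantom is a geometric surrogate for an anthropomorphic thorax: two
ellipsoidal lung fields with flattened medial faces, carved basally by a
spherical diaphragm dome, sized by bisection so the combined lung volume
hits a physical target (default 4.2 L, a typical adult male at
mid-respiration).  Ventilation defects mimicking COPD are modelled as
packed spherical lesions of reduced tracer concentration; the standard
study grid of nine distributions (uniform plus eight lesioned variants)
is exposed through :func:`spectcv.experiment.standard_distributions`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, DomainError, PackingError, SizingError
from .volumes import ActivityVolume, AttenuationMap, LungMask

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "ActivityResult",
    "build_lung_mask",
    "place_lesions",
    "build_activity",
    "total_ventilation_reduction",
    "apply_motion_blur",
    "build_attenuation",
    "MU_LUNG_CM", "MU_SOFT_TISSUE_CM",
]

# Linear attenuation coefficients at the Tc-99m photon energy (ICRU 44 regime).
MU_LUNG_CM = 0.04
MU_SOFT_TISSUE_CM = 0.16

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the two-lung voxel phantom.

    The ellipsoid semi-axes below are *unit-scale* values; a global scale
    factor is solved so the generated lung volume matches
    ``target_lung_volume_L`` to within 0.5% (contract: +/-2%).

    Parameters
    ----------
    grid_shape : (nz, ny, nx) voxels.
    voxel_pitch_mm : isotropic voxel edge, mm.
    target_lung_volume_L : combined volume of both lung fields, litres.
    lung_half_length_mm, lung_half_depth_mm, lung_half_width_mm :
        apex-base (z), antero-posterior (y) and lateral (x) semi-axes of
        each lung ellipsoid at unit scale.
    lung_separation_mm : width of the medial gap between the two lungs;
        each ellipsoid is clipped flat at the gap ("flattened medial face").
    medial_overlap_fraction : fraction of the (scaled) lateral semi-axis
        by which each ellipsoid centre is pulled towards the midline, so
        the medial clip produces a genuinely flat face.
    dome_radius_mm, dome_indent_mm : radius of the spherical diaphragm
        dome carved out of each lung base, and how deep it indents.
    body_margin_mm : soft-tissue margin of the body envelope around the
        lungs (used by the attenuation map).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_pitch_mm: float = 3.3
    target_lung_volume_L: float = 4.2
    lung_half_length_mm: float = 145.0
    lung_half_depth_mm: float = 62.0
    lung_half_width_mm: float = 52.0
    lung_separation_mm: float = 22.0
    medial_overlap_fraction: float = 0.2
    dome_radius_mm: float = 55.0
    dome_indent_mm: float = 28.0
    body_margin_mm: float = 20.0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise DomainError("grid_shape must be three positive integers")
        if not self.voxel_pitch_mm > 0:
            raise DomainError("voxel_pitch_mm must be positive")
        if not self.target_lung_volume_L > 0:
            raise DomainError("target_lung_volume_L must be positive")

    def scaled(
        self,
        factor: float,
        grid_shape: tuple[int, int, int] | None = None,
        voxel_pitch_mm: float | None = None,
    ) -> "PhantomSpec":
        """A geometrically similar phantom at ``factor`` times the linear size.

        All length parameters scale by ``factor`` and the target volume by
        ``factor**3``; the grid and pitch can be overridden independently.
        """
        if not factor > 0:
            raise DomainError("scale factor must be positive")
        return PhantomSpec(
            grid_shape=grid_shape or self.grid_shape,
            voxel_pitch_mm=voxel_pitch_mm or self.voxel_pitch_mm,
            target_lung_volume_L=self.target_lung_volume_L * factor**3,
            lung_half_length_mm=self.lung_half_length_mm * factor,
            lung_half_depth_mm=self.lung_half_depth_mm * factor,
            lung_half_width_mm=self.lung_half_width_mm * factor,
            lung_separation_mm=self.lung_separation_mm * factor,
            medial_overlap_fraction=self.medial_overlap_fraction,
            dome_radius_mm=self.dome_radius_mm * factor,
            dome_indent_mm=self.dome_indent_mm * factor,
            body_margin_mm=self.body_margin_mm * factor,
        )


@dataclass(frozen=True)
class LesionSpec:
    """Spherical-lesion population for one activity distribution.

    ``activity_fraction`` is the lesion tracer concentration relative to
    healthy lung (0 = no uptake); ``occupancy_fraction`` is the fraction
    of the lung volume occupied by lesions; ``placement`` is ``"even"``
    (quasi-uniform over the lung) or ``"clustered"`` (compact region
    around the main-bronchi landmark).
    """

    diameter_cm: float
    activity_fraction: float
    occupancy_fraction: float
    placement: str = "even"
    seed: int = 0

    def __post_init__(self):
        if not self.diameter_cm > 0:
            raise DomainError("diameter_cm must be positive")
        if not 0.0 <= self.activity_fraction <= 1.0:
            raise DomainError("activity_fraction must be in [0, 1]")
        if not 0.0 <= self.occupancy_fraction < 1.0:
            raise DomainError("occupancy_fraction must be in [0, 1)")
        if self.placement not in ("even", "clustered"):
            raise DomainError("placement must be 'even' or 'clustered'")


class ActivityResult(NamedTuple):
    volume: ActivityVolume
    occupancy_percent: float
    reduction_percent: float


# ---------------------------------------------------------------------------
# lung mask
# ---------------------------------------------------------------------------

def _lung_fields(spec: PhantomSpec, scale: float) -> np.ndarray:
    """Rasterise both lung fields at a given global scale factor."""
    nz, ny, nx = spec.grid_shape
    p = spec.voxel_pitch_mm
    cz, cy, cx = ((n - 1) / 2.0 * p for n in (nz, ny, nx))
    z = (np.arange(nz) * p - cz)[:, None, None]
    y = (np.arange(ny) * p - cy)[None, :, None]
    x = (np.arange(nx) * p - cx)[None, None, :]

    az = scale * spec.lung_half_length_mm
    ay = scale * spec.lung_half_depth_mm
    ax = scale * spec.lung_half_width_mm
    half_gap = spec.lung_separation_mm / 2.0
    dome_r = scale * spec.dome_radius_mm
    dome_cz = az + dome_r - scale * spec.dome_indent_mm

    mask = np.zeros(spec.grid_shape, dtype=bool)
    for side in (-1.0, 1.0):
        centre_x = side * (half_gap + (1.0 - spec.medial_overlap_fraction) * ax)
        ell = (z / az) ** 2 + (y / ay) ** 2 + ((x - centre_x) / ax) ** 2 <= 1.0
        ell &= side * x >= half_gap  # flattened medial face
        dome = z - dome_cz  # diaphragm dome carved from the base
        ell &= dome**2 + y**2 + (x - centre_x) ** 2 > dome_r**2
        mask |= ell
    return mask


def _required_extent_mm(spec: PhantomSpec, scale: float) -> tuple[float, float, float]:
    az = scale * spec.lung_half_length_mm
    ay = scale * spec.lung_half_depth_mm
    ax = scale * spec.lung_half_width_mm
    half_gap = spec.lung_separation_mm / 2.0
    ext_x = 2 * (half_gap + (2.0 - spec.medial_overlap_fraction) * ax)
    return 2 * az, 2 * ay, ext_x


def _fits(spec: PhantomSpec, scale: float) -> bool:
    extents = _required_extent_mm(spec, scale)
    grid = tuple(n * spec.voxel_pitch_mm for n in spec.grid_shape)
    # one-voxel clearance on each side
    return all(e <= g - 2 * spec.voxel_pitch_mm for e, g in zip(extents, grid))


def _max_scale(spec: PhantomSpec) -> float:
    """Largest global scale factor whose bounding box fits the grid."""
    p = spec.voxel_pitch_mm
    gz, gy, gx = (n * p - 2 * p for n in spec.grid_shape)
    s_z = gz / (2 * spec.lung_half_length_mm)
    s_y = gy / (2 * spec.lung_half_depth_mm)
    s_x = (gx / 2 - spec.lung_separation_mm / 2) / (
        (2.0 - spec.medial_overlap_fraction) * spec.lung_half_width_mm
    )
    return min(s_z, s_y, s_x)


@lru_cache(maxsize=32)
def _solve_scale(spec: PhantomSpec) -> float:
    """Bisection on the global scale factor to hit the target lung volume."""
    voxel_L = (spec.voxel_pitch_mm / 10.0) ** 3 / 1000.0

    def volume_L(s: float) -> float:
        return _lung_fields(spec, s).sum() * voxel_L

    s_max = _max_scale(spec)
    lo, hi = 0.05, s_max
    v_max = volume_L(s_max) if s_max > lo else 0.0
    if v_max < spec.target_lung_volume_L:
        # extrapolate the scale the target volume would need
        s_est = s_max * (spec.target_lung_volume_L / max(v_max, 1e-9)) ** (1 / 3)
        _raise_sizing(spec, min(s_est, 100.0))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        v = volume_L(mid)
        if abs(v - spec.target_lung_volume_L) <= 0.004 * spec.target_lung_volume_L:
            return mid
        if v < spec.target_lung_volume_L:
            lo = mid
        else:
            hi = mid
    raise SizingError(
        "could not match the target lung volume; the voxel pitch is too "
        "coarse for the requested volume tolerance"
    )


def _raise_sizing(spec: PhantomSpec, scale: float):
    ez, ey, ex = _required_extent_mm(spec, scale)
    need = tuple(
        int(math.ceil(e / spec.voxel_pitch_mm)) + 2 for e in (ez, ey, ex)
    )
    raise SizingError(
        f"grid {spec.grid_shape} at {spec.voxel_pitch_mm} mm cannot contain a "
        f"{spec.target_lung_volume_L} L lung; at least {need} voxels "
        f"(z, y, x) are required"
    )


def build_lung_mask(spec: PhantomSpec) -> LungMask:
    """Generate the two-lung mask for a phantom specification.

    The returned mask has exactly two face-connected components (left and
    right lung) and a physical volume within +/-2% of
    ``spec.target_lung_volume_L``.  Deterministic for a given spec.
    """
    scale = _solve_scale(spec)
    mask = _lung_fields(spec, scale)
    n_comp = ndimage.label(mask, structure=FACE_STRUCTURE)[1]
    if n_comp != 2:
        raise SizingError(
            f"phantom geometry degenerated to {n_comp} connected components; "
            "adjust the geometry parameters"
        )
    return LungMask(mask, spec.voxel_pitch_mm, variant="full")


def hilum_point(mask: LungMask) -> np.ndarray:
    """Voxel coordinates of the main-bronchi landmark.

    Defined on the synthetic phantom as the point on the mid-sagittal line
    between the lungs, at the centroid depth and at 45% of the apex-base
    extent (where the main bronchi enter the lungs).
    """
    zz, yy, xx = np.nonzero(mask.data)
    z = zz.min() + 0.45 * (zz.max() - zz.min())
    return np.array([z, yy.mean(), xx.mean()])


# ---------------------------------------------------------------------------
# lesion placement
# ---------------------------------------------------------------------------

def _sphere_voxels(centre: np.ndarray, radius_vox: float, shape) -> tuple:
    """Indices of voxels whose centres lie inside the sphere."""
    lo = np.maximum(np.floor(centre - radius_vox).astype(int), 0)
    hi = np.minimum(np.ceil(centre + radius_vox).astype(int) + 1, shape)
    if (lo >= hi).any():
        return (np.empty(0, int),) * 3
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = (
        (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
        <= radius_vox**2
    )
    return zz[inside], yy[inside], xx[inside]


class _NeighbourGrid:
    """Uniform spatial hash for incremental minimum-distance checks."""

    def __init__(self, cell: float):
        self.cell = cell
        self.cells: dict[tuple, list[np.ndarray]] = {}

    def _key(self, p):
        return tuple((p // self.cell).astype(int))

    def ok(self, p: np.ndarray, min_dist: float) -> bool:
        kz, ky, kx = self._key(p)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in self.cells.get((kz + dz, ky + dy, kx + dx), ()):
                        if np.dot(p - q, p - q) < min_dist**2 - 1e-9:
                            return False
        return True

    def add(self, p: np.ndarray):
        self.cells.setdefault(self._key(p), []).append(p)


def _component_extents_mm(mask: LungMask) -> float:
    """Smallest bounding-box extent of any lung component, mm."""
    labels, n = ndimage.label(mask.data, structure=FACE_STRUCTURE)
    widths = []
    for sl in ndimage.find_objects(labels):
        widths.extend((s.stop - s.start) * mask.voxel_pitch_mm for s in sl)
    return min(widths)


def place_lesions(mask: LungMask, lesions: LesionSpec) -> np.ndarray:
    """Draw non-overlapping lesion-sphere centres inside the lung.

    Centres (float voxel coordinates, shape ``(n, 3)``) are placed so that
    pairwise distances are at least one diameter and the rasterised lesion
    voxels occupy ``occupancy_fraction`` of the lung to within +/-0.5
    percentage points.  Lesion spheres may be clipped by the lung boundary
    (only in-lung voxels count towards occupancy).

    ``"even"`` placement is seeded rejection sampling, quasi-uniform over
    the lung, with a jittered-lattice fallback above 30% occupancy where
    random sequential packing jams.  ``"clustered"`` placement fills a
    compact region grown around the main-bronchi landmark.
    """
    pitch = mask.voxel_pitch_mm
    if lesions.occupancy_fraction == 0:
        return np.empty((0, 3))
    d_mm = lesions.diameter_cm * 10.0
    if d_mm > _component_extents_mm(mask):
        raise DomainError(
            f"lesion diameter {lesions.diameter_cm} cm exceeds the smallest "
            "lung-field width"
        )
    r_vox = d_mm / 2.0 / pitch
    d_vox = d_mm / pitch
    n_lung = mask.voxel_count
    target = lesions.occupancy_fraction * n_lung
    tol = 0.005 * n_lung
    rng = np.random.default_rng(lesions.seed)

    if lesions.placement == "clustered":
        centres = _place_clustered(mask, r_vox, d_vox, target, tol, rng)
    elif lesions.occupancy_fraction > 0.30:
        centres = _place_lattice(mask, r_vox, d_vox, target, tol, rng)
    else:
        centres = _place_rejection(mask, r_vox, d_vox, target, tol, rng)
    return np.array(centres, dtype=float).reshape(-1, 3)


def _place_rejection(mask, r_vox, d_vox, target, tol, rng):
    coords = np.argwhere(mask.data)
    taken = np.zeros(mask.shape, dtype=bool)
    grid = _NeighbourGrid(cell=max(d_vox, 1.0))
    centres: list[np.ndarray] = []
    covered = 0
    budget = int(500 * max(target / max(4 / 3 * np.pi * r_vox**3, 1.0), 10))
    for _ in range(budget):
        if covered >= target:
            break
        c = coords[rng.integers(len(coords))].astype(float)
        if not grid.ok(c, d_vox):
            continue
        vox = _sphere_voxels(c, r_vox, mask.shape)
        new = mask.data[vox] & ~taken[vox]
        gain = int(new.sum())
        if gain == 0 or covered + gain > target + tol:
            continue
        idx = tuple(a[new] for a in vox)
        taken[idx] = True
        covered += gain
        grid.add(c)
        centres.append(c)
    return _check_occupancy(centres, covered, target, tol, mask.voxel_count)


def _place_lattice(mask, r_vox, d_vox, target, tol, rng):
    # face-centred-cubic lattice with nearest-neighbour distance d: bulk
    # coverage pi*sqrt(2)/6 ~ 74%, enough headroom for high occupancies
    # where random sequential packing jams (~38%).
    a = d_vox * np.sqrt(2.0)
    best = None
    for _attempt in range(8):
        offset = rng.uniform(0, a, size=3)
        axes = [np.arange(offset[i] - a, mask.shape[i] + a, a) for i in range(3)]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        base = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
        shifts = np.array(
            [[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]
        ) * a
        sites = np.concatenate([base + sh for sh in shifts])
        nearest = np.round(sites).astype(int)
        ok = ((nearest >= 0) & (nearest < np.array(mask.shape))).all(axis=1)
        sites, nearest = sites[ok], nearest[ok]
        in_lung = mask.data[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
        sites = sites[in_lung]
        rng.shuffle(sites)
        taken = np.zeros(mask.shape, dtype=bool)
        centres, covered = [], 0
        for c in sites:
            if covered >= target:
                break
            vox = _sphere_voxels(c, r_vox, mask.shape)
            new = mask.data[vox] & ~taken[vox]
            gain = int(new.sum())
            if gain == 0 or covered + gain > target + tol:
                continue
            idx = tuple(a[new] for a in vox)
            taken[idx] = True
            covered += gain
            centres.append(c)
        if abs(covered - target) <= tol:
            return centres
        if best is None or covered > best[1]:
            best = (centres, covered)
    return _check_occupancy(best[0], best[1], target, tol, mask.voxel_count)


def _place_clustered(mask, r_vox, d_vox, target, tol, rng):
    centre = hilum_point(mask)
    coords = np.argwhere(mask.data).astype(float)
    dist = np.linalg.norm(coords - centre, axis=1)
    order = np.argsort(dist + rng.uniform(0, 0.25 * d_vox, len(dist)))
    taken = np.zeros(mask.shape, dtype=bool)
    grid = _NeighbourGrid(cell=max(d_vox, 1.0))
    centres, covered = [], 0
    for i in order:
        if covered >= target:
            break
        c = coords[i]
        if not grid.ok(c, d_vox):
            continue
        vox = _sphere_voxels(c, r_vox, mask.shape)
        new = mask.data[vox] & ~taken[vox]
        gain = int(new.sum())
        if gain == 0 or covered + gain > target + tol:
            continue
        idx = tuple(a[new] for a in vox)
        taken[idx] = True
        covered += gain
        grid.add(c)
        centres.append(c)
    return _check_occupancy(centres, covered, target, tol, mask.voxel_count)


def _check_occupancy(centres, covered, target, tol, n_lung):
    if abs(covered - target) > tol:
        raise PackingError(
            f"requested occupancy {100 * target / n_lung:.1f}% not reachable; "
            f"achieved {100 * covered / n_lung:.2f}%",
            achieved_occupancy=covered / n_lung,
        )
    return centres


# ---------------------------------------------------------------------------
# activity distributions
# ---------------------------------------------------------------------------

def build_activity(
    mask: LungMask, centres: np.ndarray, lesions: LesionSpec
) -> ActivityResult:
    """Rasterise an activity distribution from lesion centres.

    Background lung voxels get concentration 1 (arbitrary units), lesion
    voxels ``activity_fraction``, voxels outside the lung 0.  A voxel
    belongs to a lesion iff its centre lies inside a lesion sphere.
    Returns the volume together with the achieved occupancy and total
    ventilation reduction (both in percent).
    """
    centres = np.asarray(centres, dtype=float).reshape(-1, 3)
    act = np.where(mask.data, 1.0, 0.0)
    r_vox = lesions.diameter_cm * 10.0 / 2.0 / mask.voxel_pitch_mm
    lesion_vox = np.zeros(mask.shape, dtype=bool)
    for c in centres:
        nearest = tuple(np.clip(np.round(c).astype(int), 0, np.array(mask.shape) - 1))
        if not mask.data[nearest]:
            raise ConsistencyError(f"lesion centre {c} lies outside the lung mask")
        vox = _sphere_voxels(c, r_vox, mask.shape)
        lesion_vox[vox] = True
    lesion_vox &= mask.data
    act[lesion_vox] = lesions.activity_fraction
    occupancy = lesion_vox.sum() / mask.voxel_count
    reduction = 100.0 * occupancy * (1.0 - lesions.activity_fraction)
    return ActivityResult(
        ActivityVolume(act, mask.voxel_pitch_mm, provenance="phantom"),
        100.0 * occupancy,
        reduction,
    )


def total_ventilation_reduction(
    occupancy_fraction: float, activity_fraction: float
) -> float:
    """Total reduction of functioning lung, in percent.

    A fraction ``occupancy_fraction`` of the lung ventilates at
    ``activity_fraction`` of the healthy level, so the functional loss is
    ``100 * occupancy * (1 - activity)``.
    """
    if not 0.0 <= occupancy_fraction <= 1.0:
        raise DomainError("occupancy_fraction must be in [0, 1]")
    if not 0.0 <= activity_fraction <= 1.0:
        raise DomainError("activity_fraction must be in [0, 1]")
    return 100.0 * occupancy_fraction * (1.0 - activity_fraction)


# ---------------------------------------------------------------------------
# motion blur and attenuation
# ---------------------------------------------------------------------------

def apply_motion_blur(
    activity: ActivityVolume,
    basal_amplitude_mm: float,
    apical_amplitude_mm: float = 0.0,
    n_phases: int = 24,
) -> ActivityVolume:
    """Respiratory-motion surrogate: cyclic axial displacement, time-averaged.

    Each transaxial plane at depth ``z`` is displaced axially by
    ``A(z) * sin(phase)`` where the amplitude ``A`` interpolates linearly
    from ``apical_amplitude_mm`` at the apex (z index 0) to
    ``basal_amplitude_mm`` at the base, and the result is averaged over a
    full cycle.  A Jacobian weight compensates the axial compression/
    dilation of the displacement field so total activity is conserved
    (to <0.1%, edge losses excluded by zero padding).
    """
    if basal_amplitude_mm < 0 or apical_amplitude_mm < 0:
        raise DomainError("amplitudes must be >= 0")
    if basal_amplitude_mm < apical_amplitude_mm:
        raise DomainError("basal amplitude must be >= apical amplitude")
    if basal_amplitude_mm == 0:
        return ActivityVolume(
            activity.data.copy(), activity.voxel_pitch_mm, activity.provenance
        )
    pitch = activity.voxel_pitch_mm
    nz = activity.shape[0]
    pad = int(np.ceil(basal_amplitude_mm / pitch)) + 1
    data = np.pad(activity.data, ((pad, pad), (0, 0), (0, 0)))
    npz = data.shape[0]
    # amplitude (voxels) on the padded axis; linear in the original z
    z_orig = np.clip(np.arange(npz) - pad, 0, nz - 1)
    amp = (
        apical_amplitude_mm
        + (basal_amplitude_mm - apical_amplitude_mm) * z_orig / max(nz - 1, 1)
    ) / pitch
    damp_dz = np.gradient(amp)

    flat = data.reshape(npz, -1)
    out = np.zeros_like(flat)
    phases = 2 * np.pi * (np.arange(n_phases) + 0.5) / n_phases
    z_idx = np.arange(npz)
    for ph in phases:
        s = np.sin(ph)
        src = z_idx - amp * s
        k = np.clip(np.floor(src).astype(int), 0, npz - 2)
        w = src - k
        jac = 1.0 - damp_dz * s
        out += jac[:, None] * ((1 - w)[:, None] * flat[k] + w[:, None] * flat[k + 1])
    out /= n_phases
    result = out.reshape(data.shape)[pad:-pad]
    return ActivityVolume(result, pitch, provenance=activity.provenance)


def build_attenuation(spec: PhantomSpec, mask: LungMask) -> AttenuationMap:
    """Attenuation map: lung 0.04 cm^-1, soft-tissue body envelope 0.16, air 0.

    The body envelope is an elliptic cylinder fitted around the lung mask
    with a soft-tissue margin, closed above the apex and below the base.
    Lesions share the lung attenuation (their density is taken equal to
    healthy lung tissue).
    """
    if mask.shape != tuple(spec.grid_shape):
        raise ConsistencyError("spec and mask grids differ")
    pitch = spec.voxel_pitch_mm
    margin_vox = spec.body_margin_mm / pitch
    zz, yy, xx = np.nonzero(mask.data)
    cy, cx = (yy.min() + yy.max()) / 2.0, (xx.min() + xx.max()) / 2.0
    ry = (yy.max() - yy.min()) / 2.0 + margin_vox
    rx = (xx.max() - xx.min()) / 2.0 + margin_vox
    z0 = max(zz.min() - margin_vox, 0)
    z1 = min(zz.max() + 1.5 * margin_vox, spec.grid_shape[0] - 1)
    z = np.arange(spec.grid_shape[0])[:, None, None]
    y = np.arange(spec.grid_shape[1])[None, :, None]
    x = np.arange(spec.grid_shape[2])[None, None, :]
    body = (((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0) & (z >= z0) & (z <= z1)
    mu = np.zeros(spec.grid_shape)
    mu[body] = MU_SOFT_TISSUE_CM
    mu[mask.data] = MU_LUNG_CM
    return AttenuationMap(mu, pitch)
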