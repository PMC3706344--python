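"""The core inhomogeneity statistic: sliding-kernel CV maps and AUC(CV_T).

A cubic kernel (default side 3 cm) steps voxel-by-voxel through the
reconstructed ventilation volume.  At every position whose centre voxel
lies in the analysis (peeled-lung) mask, the coefficient of variance

    CV = 100 * SD / mean   [percent]

is computed over the in-mask voxels inside the kernel (sample SD, n-1
denominator) and stored at the kernel centre, giving the *CV matrix*.
The CV values of a volume are summarised as a *frequency function*: a
histogram in 1%-wide bins normalised to a total area of 100%.  A healthy
reference group defines the threshold ``CV_T`` as the modal value of its
mean frequency function, and a volume's global inhomogeneity score is

    AUC(CV_T) = percentage of its CV values strictly greater than CV_T,

so 100% is maximal measured inhomogeneity and a healthy volume scores
near 50% (about half its CV values exceed its own mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import AnalysisError, SettingsError, ShapeError
from .volumes import ActivityVolume, LungMask

__all__ = [
    "CVSettings",
    "CVMatrix",
    "FrequencyFunction",
    "AnalysisResult",
    "cv_kernel",
    "frequency_function",
    "modal_cvt",
    "auc_above",
    "analyze_volume",
]


@dataclass(frozen=True)
class CVSettings:
    """Kernel size, histogram binning and kernel-validity floor.

    ``kernel_side_cm`` is converted to voxels as
    ``round(kernel_side_cm * 10 / pitch_mm)`` forced odd (e.g. 3 cm at a
    3.3 mm pitch gives a 9 x 9 x 9 = 729-voxel kernel).  A kernel position
    needs at least ``min_kernel_voxels`` in-mask voxels for the sample SD
    to be defined.
    """

    kernel_side_cm: float = 3.0
    bin_width_percent: float = 1.0
    min_kernel_voxels: int = 2

    def __post_init__(self):
        if not self.kernel_side_cm > 0:
            raise SettingsError("kernel side must be positive")
        if not self.bin_width_percent > 0:
            raise SettingsError("bin width must be positive")
        if self.min_kernel_voxels < 2:
            raise SettingsError("at least 2 voxels are needed for a sample SD")

    def kernel_voxels(self, voxel_pitch_mm: float) -> int:
        """Odd kernel side length in voxels for a given grid pitch."""
        target = self.kernel_side_cm * 10.0 / voxel_pitch_mm
        k = int(round(target))
        if k % 2 == 0:
            k = k + 1 if target >= k else k - 1
        return max(k, 1)


@dataclass
class CVMatrix:
    """CV values (percent) stored at valid kernel centres; NaN elsewhere."""

    values: np.ndarray
    valid: np.ndarray
    settings: CVSettings
    voxel_pitch_mm: float

    @property
    def cv_values(self) -> np.ndarray:
        """The valid CV values as a flat array (percent)."""
        return self.values[self.valid]

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class FrequencyFunction:
    """Histogram of CV values in fixed-width bins, area-normalised to 100%.

    ``bin_left`` holds the left edges (percent, first edge at 0); bins are
    half-open ``[left, left + width)``.
    """

    bin_left: np.ndarray
    frequencies_percent: np.ndarray
    bin_width_percent: float = 1.0

    def __post_init__(self):
        self.bin_left = np.asarray(self.bin_left, dtype=float)
        self.frequencies_percent = np.asarray(self.frequencies_percent, dtype=float)
        if self.bin_left.shape != self.frequencies_percent.shape:
            raise ShapeError("bin edges and frequencies must align")

    @property
    def bin_midpoints(self) -> np.ndarray:
        return self.bin_left + 0.5 * self.bin_width_percent


@dataclass
class AnalysisResult:
    """Per-volume summary: threshold, score and the volumes analysed."""

    cv_t_percent: float
    auc_percent: float
    n_valid_cv: int
    lung_volume_L: float
    peeled_volume_L: float


def cv_kernel(
    vol: ActivityVolume, mask: LungMask, settings: CVSettings | None = None
) -> CVMatrix:
    """Sliding-kernel CV matrix of a volume over an analysis mask.

    For every voxel of ``mask``, CV (percent) is computed over the
    in-mask voxels inside the cubic kernel centred there, with the sample
    (n-1) standard deviation.  Positions with fewer than
    ``settings.min_kernel_voxels`` in-mask voxels, or zero mean, are
    invalid.  Voxels outside the mask never contribute.
    """
    settings = settings or CVSettings()
    if vol.shape != mask.shape:
        raise ShapeError("volume and mask grids differ")
    k = settings.kernel_voxels(vol.voxel_pitch_mm)
    if any(k > n for n in vol.shape):
        raise SettingsError(
            f"kernel of {k} voxels exceeds the grid extent {vol.shape}"
        )
    m = mask.data.astype(np.float64)
    x = vol.data * m
    size = (k, k, k)
    kvol = float(k**3)
    # uniform_filter returns kernel means; rescale to kernel sums
    n_in = np.round(ndimage.uniform_filter(m, size=size, mode="constant") * kvol)
    s1 = ndimage.uniform_filter(x, size=size, mode="constant") * kvol
    s2 = ndimage.uniform_filter(x * x, size=size, mode="constant") * kvol

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / n_in
        var = (s2 - s1 * s1 / n_in) / (n_in - 1)
        cv = 100.0 * np.sqrt(np.maximum(var, 0.0)) / mean
    valid = mask.data & (n_in >= settings.min_kernel_voxels) & (mean > 0)
    values = np.full(vol.shape, np.nan)
    values[valid] = cv[valid]
    return CVMatrix(values, valid, settings, vol.voxel_pitch_mm)


def frequency_function(
    cvm: CVMatrix, settings: CVSettings | None = None
) -> FrequencyFunction:
    """Histogram the CV values of a matrix into the standard binning."""
    settings = settings or cvm.settings
    vals = cvm.cv_values
    if vals.size == 0:
        raise AnalysisError("no valid CV values to histogram")
    w = settings.bin_width_percent
    n_bins = int(np.floor(vals.max() / w)) + 1
    edges = np.arange(n_bins + 1) * w
    hist, _ = np.histogram(vals, bins=edges)
    freq = 100.0 * hist / vals.size
    return FrequencyFunction(edges[:-1], freq, bin_width_percent=w)


def mean_frequency_function(ffs: Sequence[FrequencyFunction]) -> FrequencyFunction:
    """Arithmetic mean of frequency functions on identical binning."""
    if len(ffs) == 0:
        raise AnalysisError("need at least one frequency function")
    w = ffs[0].bin_width_percent
    for ff in ffs:
        if abs(ff.bin_width_percent - w) > 1e-12 or (
            ff.bin_left.size and abs(ff.bin_left[0]) > 1e-12
        ):
            raise SettingsError("frequency functions use inconsistent binning")
    n = max(ff.bin_left.size for ff in ffs)
    acc = np.zeros(n)
    for ff in ffs:
        acc[: ff.frequencies_percent.size] += ff.frequencies_percent
    return FrequencyFunction(np.arange(n) * w, acc / len(ffs), bin_width_percent=w)


def modal_cvt(healthy_ffs: Sequence[FrequencyFunction]) -> float:
    """CV threshold: modal-bin midpoint of a healthy group's mean function.

    Ties between equally tall bins break towards the lower bin.
    """
    mean_ff = mean_frequency_function(healthy_ffs)
    peak = int(np.argmax(mean_ff.frequencies_percent))  # argmax takes lowest tie
    return float(mean_ff.bin_left[peak] + 0.5 * mean_ff.bin_width_percent)


def auc_above(cvm: CVMatrix, cvt: float) -> float:
    """AUC(CV_T): percent of valid CV values strictly greater than ``cvt``."""
    if cvt < 0:
        raise AnalysisError("cvt must be >= 0")
    vals = cvm.cv_values
    if vals.size == 0:
        raise AnalysisError("empty CV matrix")
    return 100.0 * float((vals > cvt).sum()) / vals.size


def analyze_volume(
    recon: ActivityVolume,
    full_mask: LungMask,
    settings: CVSettings | None = None,
    peel_layers: int = 1,
    cvt: float | None = None,
) -> tuple[AnalysisResult, CVMatrix, FrequencyFunction]:
    """End-to-end single-volume analysis: peel, CV map, histogram, score.

    If ``cvt`` is None the volume's own modal CV is used as its threshold
    (appropriate only for a healthy reference volume).
    """
    from .lungseg import peel as _peel

    settings = settings or CVSettings()
    peeled_mask, _removed = _peel(full_mask, peel_layers)
    cvm = cv_kernel(recon, peeled_mask, settings)
    ff = frequency_function(cvm, settings)
    if cvt is None:
        cvt = modal_cvt([ff])
    auc = auc_above(cvm, cvt)
    result = AnalysisResult(
        cv_t_percent=float(cvt),
        auc_percent=auc,
        n_valid_cv=cvm.n_valid,
        lung_volume_L=full_mask.volume_L,
        peeled_volume_L=peeled_mask.volume_L,
    )
    return result, cvm, ff
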