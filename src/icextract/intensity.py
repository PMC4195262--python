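"""Tissue-based intensity normalization.

Patch similarity is intensity-driven, so subject and template library must
share one intensity scale.  Robust mean intensities of CSF, grey matter and
white matter are estimated inside a brain region of interest with an
alternating assignment / trimmed-mean scheme, then a piecewise-linear map
anchors those means at 50 / 150 / 250 normalized units (the T1-weighted
contrast ordering CSF < GM < WM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, IntensityVolume

__all__ = [
    "TissueMeans",
    "IntensityMap",
    "estimate_tissue_means",
    "build_intensity_map",
    "apply_intensity_map",
    "normalize_volume",
]

#: Normalized target intensities for (CSF, GM, WM).
TARGET_ANCHORS = (50.0, 150.0, 250.0)


class TissueEstimationError(ValueError):
    """Tissue means could not be estimated from the given region."""


@dataclass(frozen=True)
class TissueMeans:
    """Robust mean intensities of the three head tissues, in input units."""

    csf_mean: float
    gm_mean: float
    wm_mean: float

    def __post_init__(self) -> None:
        if not (0 < self.csf_mean < self.gm_mean < self.wm_mean):
            raise ValueError(
                "tissue means must satisfy 0 < CSF < GM < WM, got "
                f"({self.csf_mean}, {self.gm_mean}, {self.wm_mean})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.csf_mean, self.gm_mean, self.wm_mean])


@dataclass(frozen=True)
class IntensityMap:
    """Monotone piecewise-linear intensity mapping.

    Control points are (0, 0), (csf, 50), (gm, 150), (wm, 250); above the
    WM anchor the last segment's slope is extended, below zero the output
    is clamped at 0.
    """

    sources: tuple[float, ...]
    targets: tuple[float, ...]

    def __post_init__(self) -> None:
        src = np.asarray(self.sources)
        tgt = np.asarray(self.targets)
        if len(src) != len(tgt) or len(src) < 2:
            raise ValueError("map needs matching source/target control points")
        if not np.all(np.diff(src) > 0):
            raise ValueError("source intensities must be strictly increasing")
        if not np.all(np.diff(tgt) >= 0):
            raise ValueError("map must be monotone non-decreasing")

    def __call__(self, values: np.ndarray | float) -> np.ndarray | float:
        src = np.asarray(self.sources)
        tgt = np.asarray(self.targets)
        v = np.asarray(values, dtype=np.float64)
        out = np.interp(v, src, tgt)
        # extend the final segment's slope beyond the WM anchor
        slope = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
        above = v > src[-1]
        if np.any(above):
            out = np.where(above, tgt[-1] + slope * (v - src[-1]), out)
        out = np.maximum(out, 0.0)
        return float(out) if np.isscalar(values) else out


def _trimmed_mean(values: np.ndarray, center: float, trim_fraction: float) -> float:
    """Mean of ``values`` after discarding the ``trim_fraction`` of points
    farthest from ``center``."""
    n = values.size
    keep = max(1, int(np.ceil((1.0 - trim_fraction) * n)))
    if keep >= n:
        return float(values.mean())
    order = np.argsort(np.abs(values - center), kind="stable")
    return float(values[order[:keep]].mean())


def estimate_tissue_means(
    volume: IntensityVolume,
    roi: BinaryMask,
    trim_fraction: float = 0.2,
    max_iter: int = 100,
    tol: float = 0.01,
) -> TissueMeans:
    """Estimate robust CSF/GM/WM mean intensities inside ``roi``.

    Alternates (a) assigning each ROI voxel to the nearest current class
    mean and (b) recomputing each mean as a trimmed mean of its assigned
    voxels, discarding the ``trim_fraction`` farthest from the current
    mean — the trimming suppresses partial-volume voxels that lie between
    the pure-tissue modes.  Means are initialized at the 10th/50th/90th
    intensity percentiles of the ROI and iterated until every mean moves
    by less than ``tol``.
    """
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if volume.shape != roi.shape:
        raise ValueError(f"volume shape {volume.shape} != roi shape {roi.shape}")
    values = volume.data[roi.data > 0]
    if values.size == 0:
        raise TissueEstimationError("ROI is empty")
    if np.unique(values).size < 3:
        raise TissueEstimationError(
            "ROI holds fewer than 3 distinct intensity levels; cannot "
            "separate CSF/GM/WM"
        )
    means = np.percentile(values, [10, 50, 90]).astype(np.float64)
    for _ in range(max_iter):
        # nearest-mean assignment
        assign = np.argmin(np.abs(values[:, None] - means[None, :]), axis=1)
        new_means = means.copy()
        for k in range(3):
            cls = values[assign == k]
            if cls.size == 0:
                raise TissueEstimationError(
                    f"tissue class {k} lost all voxels during estimation"
                )
            new_means[k] = _trimmed_mean(cls, means[k], trim_fraction)
        moved = np.max(np.abs(new_means - means))
        means = new_means
        if moved < tol:
            break
    if not (means[0] < means[1] < means[2]):
        raise TissueEstimationError(
            f"estimated means are not ordered CSF < GM < WM: {tuple(means)}"
        )
    return TissueMeans(float(means[0]), float(means[1]), float(means[2]))


def build_intensity_map(means: TissueMeans) -> IntensityMap:
    """Build the piecewise-linear map taking the estimated tissue means to
    the normalized anchors (CSF, GM, WM) -> (50, 150, 250), anchored
    through the origin below CSF."""
    return IntensityMap(
        sources=(0.0, means.csf_mean, means.gm_mean, means.wm_mean),
        targets=(0.0,) + TARGET_ANCHORS,
    )


def apply_intensity_map(volume: IntensityVolume, imap: IntensityMap) -> IntensityVolume:
    """Map every voxel through ``imap``; shape and geometry preserved."""
    return IntensityVolume(imap(volume.data), volume.voxel_size_mm, volume.affine)


def normalize_volume(
    volume: IntensityVolume,
    roi: BinaryMask,
    trim_fraction: float = 0.2,
) -> tuple[IntensityVolume, TissueMeans]:
    """Convenience wrapper: estimate means in ``roi``, build the map and
    apply it.  Returns the normalized volume and the estimated means."""
    means = estimate_tissue_means(volume, roi, trim_fraction)
    return apply_intensity_map(volume, build_intensity_map(means)), means
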