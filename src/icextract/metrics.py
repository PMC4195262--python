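"""Segmentation accuracy and reproducibility measures.

Overlap is summarized by the Dice coefficient 2|A∩B|/(|A|+|B|) plus
sensitivity and specificity against a reference mask; volume agreement by
the symmetric percent volume difference and the Pearson correlation of
volume series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask

__all__ = [
    "OverlapReport",
    "dice",
    "overlap",
    "percent_volume_difference",
    "volume_correlation",
]


@dataclass(frozen=True)
class OverlapReport:
    dice: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    fn: int
    tn: int
    volume_a_ml: float
    volume_b_ml: float


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient; two empty masks agree perfectly (Dice 1)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def overlap(
    a: BinaryMask,
    b: BinaryMask,
    voxel_size_mm: tuple[float, float, float] | None = None,
) -> OverlapReport:
    """Full overlap report of mask ``a`` against reference ``b``.

    Sensitivity = tp/(tp+fn) and specificity = tn/(tn+fp) with ``b`` as
    the reference; an empty reference makes sensitivity undefined and is
    an error.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if b.count() == 0:
        raise ValueError("reference mask is empty; sensitivity is undefined")
    vsize = voxel_size_mm if voxel_size_mm is not None else a.voxel_size_mm
    va = a.data > 0
    vb = b.data > 0
    tp = int(np.sum(va & vb))
    fp = int(np.sum(va & ~vb))
    fn = int(np.sum(~va & vb))
    tn = int(np.sum(~va & ~vb))
    voxel_ml = float(np.prod(vsize)) / 1000.0
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    return OverlapReport(
        dice=2.0 * tp / (2 * tp + fp + fn),
        sensitivity=tp / (tp + fn),
        specificity=specificity,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        volume_a_ml=(tp + fp) * voxel_ml,
        volume_b_ml=(tp + fn) * voxel_ml,
    )


def percent_volume_difference(
    v1_ml: float, v2_ml: float, symmetric: bool = True
) -> float:
    """Percent volume difference between two positive volumes.

    Default is the symmetrized form 100*|v1-v2| / ((v1+v2)/2); with
    ``symmetric=False`` the first argument anchors the denominator.
    """
    if v1_ml <= 0 or v2_ml <= 0:
        raise ValueError("volumes must be positive")
    denom = (v1_ml + v2_ml) / 2.0 if symmetric else v1_ml
    return 100.0 * abs(v1_ml - v2_ml) / denom


def volume_correlation(estimates, references) -> float:
    """Pearson correlation between estimated and reference volume series."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be 1D of equal length")
    if est.size < 3:
        raise ValueError("need at least 3 volume pairs")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise ValueError("correlation is undefined for a constant series")
    return float(np.corrcoef(est, ref)[0, 1])
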