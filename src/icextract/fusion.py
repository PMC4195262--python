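"""Nonlocal patch-based label fusion.

The vote for a voxel is a weighted average of binary labels carried by
similar patches found across the selected templates, within a bounded
search window around the corresponding grid location:

    v(x_i) = sum_s sum_{j in V_i} w(x_i, x_{s,j}) * l_{s,j}
             / sum_s sum_{j in V_i} w(x_i, x_{s,j})

Two weight models are provided.  The *classical* (voxelwise baseline)
weight depends on patch intensity distance alone,

    w = exp(-d2 / h^2),       d2 = ||P(x_i) - P(x_{s,j})||^2 / |P|,

while the *bilateral* weight adds a spatial-proximity term that encodes a
locality principle valid after linear registration to a common space,

    w = exp(-(|x_i - x_j| / sigma_d + d2 / h)),

with |x_i - x_j| the Euclidean distance between patch centers in mm.
Both are gated by a cheap structural-similarity preselection (mean/std
ratio product >= ss_threshold) and share the adaptive bandwidth

    h(x_i) = lambda * min_{s,j} d2(x_i, x_{s,j}) + epsilon.

Blockwise voting assigns one weight per candidate to the candidate's whole
label block; per-voxel votes are then recovered in an overcomplete manner
by averaging over all covering blocks, which both regularizes the labels
and — with a block spacing of 2 voxels — cuts the number of weight
evaluations by 2^3 = 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import BinaryMask, FusionConfig, IntensityVolume, TemplateLibrary, VoteVolume

__all__ = [
    "Patch",
    "extract_patch",
    "structural_similarity",
    "patch_distance",
    "adaptive_h",
    "bilateral_weight",
    "classical_weight",
    "block_center_grid",
    "voxelwise_fusion",
    "blockwise_fusion",
    "threshold_votes",
]


# ---------------------------------------------------------------------------
# Patch-level operations (reference definitions; the production path below
# re-expresses the same formulas inside a compiled kernel).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Patch:
    """Flattened cubic intensity neighborhood with its center and moments."""

    values: np.ndarray
    center_index: tuple[int, int, int]
    mean: float
    std: float

    @classmethod
    def from_values(
        cls, values: np.ndarray, center_index: tuple[int, int, int]
    ) -> "Patch":
        v = np.asarray(values, dtype=np.float64).ravel()
        return cls(v, tuple(int(c) for c in center_index), float(v.mean()), float(v.std()))


def extract_patch(
    volume: IntensityVolume, center: tuple[int, int, int], radius: int
) -> Patch:
    """Cubic patch of edge ``2*radius+1`` around ``center``, clipped to the
    grid (no padding is invented at the image border)."""
    x, y, z = (int(c) for c in center)
    X, Y, Z = volume.shape
    sl = tuple(
        slice(max(c - radius, 0), min(c + radius, s - 1) + 1)
        for c, s in ((x, X), (y, Y), (z, Z))
    )
    return Patch.from_values(volume.data[sl], (x, y, z))


def _ratio_term(a: float, b: float) -> float:
    # 2ab/(a^2+b^2); 1 when both vanish, 0 when exactly one does.
    if a == 0.0 and b == 0.0:
        return 1.0
    if a == 0.0 or b == 0.0:
        return 0.0
    return 2.0 * a * b / (a * a + b * b)


def structural_similarity(p: Patch, q: Patch) -> float:
    """Mean/std structural-similarity score in [0, 1] used for candidate
    preselection: ss = (2*mu_p*mu_q/(mu_p^2+mu_q^2)) * (2*sd_p*sd_q/(sd_p^2+sd_q^2))."""
    return _ratio_term(p.mean, q.mean) * _ratio_term(p.std, q.std)


def patch_distance(p: Patch, q: Patch) -> float:
    """Squared L2 patch distance normalized by the number of elements."""
    if p.values.shape != q.values.shape:
        raise ValueError(
            f"patch length mismatch: {p.values.size} vs {q.values.size}"
        )
    diff = p.values - q.values
    return float(diff @ diff) / p.values.size


def adaptive_h(
    target: Patch,
    candidates: list[Patch],
    lambda_h: float,
    epsilon_h: float,
) -> float:
    """Adaptive bandwidth h = lambda * (minimum normalized squared patch
    distance to any candidate) + epsilon; strictly positive."""
    if not candidates:
        raise ValueError("candidate set is empty")
    dmin = min(patch_distance(target, q) for q in candidates)
    return lambda_h * dmin + epsilon_h


def bilateral_weight(
    target: Patch,
    candidate: Patch,
    h: float,
    sigma_d_mm: float,
    ss_threshold: float,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Bilateral (spatial + intensity) similarity weight in [0, 1].

    Zero when the structural-similarity preselection fails; otherwise
    exp(-(center distance in mm / sigma_d + patch distance / h)).
    """
    if h <= 0 or sigma_d_mm <= 0:
        raise ValueError("h and sigma_d_mm must be positive")
    if structural_similarity(target, candidate) < ss_threshold:
        return 0.0
    delta = [
        (a - b) * s
        for a, b, s in zip(target.center_index, candidate.center_index, voxel_size_mm)
    ]
    spatial = math.sqrt(sum(d * d for d in delta))
    return math.exp(-(spatial / sigma_d_mm + patch_distance(target, candidate) / h))


def classical_weight(
    target: Patch,
    candidate: Patch,
    h: float,
    ss_threshold: float,
) -> float:
    """Baseline intensity-only weight exp(-patch distance / h^2), with the
    same structural-similarity gate as the bilateral weight."""
    if h <= 0:
        raise ValueError("h must be positive")
    if structural_similarity(target, candidate) < ss_threshold:
        return 0.0
    return math.exp(-patch_distance(target, candidate) / (h * h))


# ---------------------------------------------------------------------------
# Block grid construction
# ---------------------------------------------------------------------------


def _axis_centers(length: int, spacing: int, block_radius: int) -> np.ndarray:
    """Block-center positions along one axis: every ``spacing``-th voxel,
    plus the last fully in-bounds center if the tail would otherwise be
    uncovered."""
    pos = list(range(0, length, spacing))
    if pos[-1] + block_radius < length - 1:
        tail = max(0, length - 1 - block_radius)
        if tail != pos[-1]:
            pos.append(tail)
    return np.asarray(pos, dtype=np.int64)


def block_center_grid(
    shape: tuple[int, int, int],
    block_spacing: int,
    block_radius: int,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """(M, 3) int64 array of block-center coordinates.

    Centers lie on a regular ``block_spacing`` grid per axis (plus a tail
    center so blocks cover the full extent).  When ``roi`` is given, only
    centers whose block (Chebyshev radius ``block_radius``) intersects the
    ROI are kept.
    """
    if block_spacing < 1:
        raise ValueError("block_spacing must be positive")
    axes = [_axis_centers(s, block_spacing, block_radius) for s in shape]
    cx, cy, cz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    if roi is not None:
        roi = np.asarray(roi) > 0
        if block_radius > 0:
            from scipy.ndimage import maximum_filter

            reach = maximum_filter(roi, size=2 * block_radius + 1, mode="constant")
        else:
            reach = roi
        keep = reach[centers[:, 0], centers[:, 1], centers[:, 2]]
        centers = centers[keep]
    return np.ascontiguousarray(centers)


# ---------------------------------------------------------------------------
# Compiled fusion kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fuse_kernel(
    img,  # (X,Y,Z) f8 subject intensities
    tmpl,  # (N,X,Y,Z) f8 template intensities
    labs,  # (N,X,Y,Z) u1 template labels
    centers,  # (M,3) i8 target centers
    patch_radius,
    search_radius,
    block_radius,
    lambda_h,
    epsilon_h,
    sigma_d_mm,
    ss_threshold,
    vsx,
    vsy,
    vsz,
    bilateral,  # bool: bilateral weight vs classical exp(-d2/h^2)
    num,  # (X,Y,Z) f8 out: weighted label accumulator
    mass,  # (X,Y,Z) f8 out: weight accumulator
    ctr_zero,  # (M,) u1 out: 1 where total weight at the center was zero
    ctr_major,  # (M,) u1 out: majority center label for fallback
):
    X, Y, Z = img.shape
    N = tmpl.shape[0]
    M = centers.shape[0]
    win = 2 * search_radius + 1
    max_cand = N * win * win * win
    d2buf = np.empty(max_cand, dtype=np.float64)
    okbuf = np.empty(max_cand, dtype=np.uint8)
    coords = np.empty((max_cand, 4), dtype=np.int64)

    for m in range(M):
        cx, cy, cz = centers[m, 0], centers[m, 1], centers[m, 2]
        # target patch offsets, clipped to the grid
        lx = min(patch_radius, cx)
        ux = min(patch_radius, X - 1 - cx)
        ly = min(patch_radius, cy)
        uy = min(patch_radius, Y - 1 - cy)
        lz = min(patch_radius, cz)
        uz = min(patch_radius, Z - 1 - cz)
        npix = (lx + ux + 1) * (ly + uy + 1) * (lz + uz + 1)
        tsum = 0.0
        tsq = 0.0
        for dx in range(-lx, ux + 1):
            for dy in range(-ly, uy + 1):
                for dz in range(-lz, uz + 1):
                    v = img[cx + dx, cy + dy, cz + dz]
                    tsum += v
                    tsq += v * v
        tmean = tsum / npix
        tvar = tsq / npix - tmean * tmean
        tstd = math.sqrt(tvar) if tvar > 0.0 else 0.0

        # candidate window per axis: inside the search radius AND such that
        # every target patch offset stays in-bounds at the candidate
        jx0 = max(cx - search_radius, lx)
        jx1 = min(cx + search_radius, X - 1 - ux)
        jy0 = max(cy - search_radius, ly)
        jy1 = min(cy + search_radius, Y - 1 - uy)
        jz0 = max(cz - search_radius, lz)
        jz1 = min(cz + search_radius, Z - 1 - uz)

        ncand = 0
        dmin = np.inf
        n_lab1 = 0
        for s in range(N):
            for jx in range(jx0, jx1 + 1):
                for jy in range(jy0, jy1 + 1):
                    for jz in range(jz0, jz1 + 1):
                        csum = 0.0
                        csq = 0.0
                        d2 = 0.0
                        for dx in range(-lx, ux + 1):
                            for dy in range(-ly, uy + 1):
                                for dz in range(-lz, uz + 1):
                                    a = img[cx + dx, cy + dy, cz + dz]
                                    b = tmpl[s, jx + dx, jy + dy, jz + dz]
                                    csum += b
                                    csq += b * b
                                    d2 += (a - b) * (a - b)
                        d2 /= npix
                        if d2 < dmin:
                            dmin = d2
                        cmean = csum / npix
                        cvar = csq / npix - cmean * cmean
                        cstd = math.sqrt(cvar) if cvar > 0.0 else 0.0
                        # structural-similarity gate
                        if tmean == 0.0 and cmean == 0.0:
                            mu_term = 1.0
                        elif tmean == 0.0 or cmean == 0.0:
                            mu_term = 0.0
                        else:
                            mu_term = (
                                2.0 * tmean * cmean / (tmean * tmean + cmean * cmean)
                            )
                        if tstd == 0.0 and cstd == 0.0:
                            sd_term = 1.0
                        elif tstd == 0.0 or cstd == 0.0:
                            sd_term = 0.0
                        else:
                            sd_term = 2.0 * tstd * cstd / (tstd * tstd + cstd * cstd)
                        ss = mu_term * sd_term
                        d2buf[ncand] = d2
                        okbuf[ncand] = 1 if ss >= ss_threshold else 0
                        coords[ncand, 0] = s
                        coords[ncand, 1] = jx
                        coords[ncand, 2] = jy
                        coords[ncand, 3] = jz
                        if labs[s, jx, jy, jz] == 1:
                            n_lab1 += 1
                        ncand += 1

        h = lambda_h * dmin + epsilon_h
        wtotal = 0.0
        for k in range(ncand):
            if okbuf[k] == 0:
                continue
            s = coords[k, 0]
            jx = coords[k, 1]
            jy = coords[k, 2]
            jz = coords[k, 3]
            d2 = d2buf[k]
            if bilateral:
                ddx = (jx - cx) * vsx
                ddy = (jy - cy) * vsy
                ddz = (jz - cz) * vsz
                spatial = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
                w = math.exp(-(spatial / sigma_d_mm + d2 / h))
            else:
                w = math.exp(-d2 / (h * h))
            if w <= 0.0:
                continue
            wtotal += w
            # scatter the weight over the candidate's label block, clipped
            # so both the target block and the label block stay in-bounds
            bx0 = -min(block_radius, cx, jx)
            bx1 = min(block_radius, X - 1 - cx, X - 1 - jx)
            by0 = -min(block_radius, cy, jy)
            by1 = min(block_radius, Y - 1 - cy, Y - 1 - jy)
            bz0 = -min(block_radius, cz, jz)
            bz1 = min(block_radius, Z - 1 - cz, Z - 1 - jz)
            for dx in range(bx0, bx1 + 1):
                for dy in range(by0, by1 + 1):
                    for dz in range(bz0, bz1 + 1):
                        num[cx + dx, cy + dy, cz + dz] += (
                            w * labs[s, jx + dx, jy + dy, jz + dz]
                        )
                        mass[cx + dx, cy + dy, cz + dz] += w

        if wtotal == 0.0:
            ctr_zero[m] = 1
            # majority label of candidate centers; ties -> 0
            ctr_major[m] = 1 if 2 * n_lab1 > ncand else 0


@njit(cache=True)
def _apply_fallback(
    centers, ctr_zero, ctr_major, block_radius, mass, votes, processed, fallback
):
    X, Y, Z = mass.shape
    for m in range(centers.shape[0]):
        if ctr_zero[m] == 0:
            continue
        cx, cy, cz = centers[m, 0], centers[m, 1], centers[m, 2]
        for dx in range(-min(block_radius, cx), min(block_radius, X - 1 - cx) + 1):
            for dy in range(-min(block_radius, cy), min(block_radius, Y - 1 - cy) + 1):
                for dz in range(
                    -min(block_radius, cz), min(block_radius, Z - 1 - cz) + 1
                ):
                    x, y, z = cx + dx, cy + dy, cz + dz
                    if mass[x, y, z] == 0.0 and fallback[x, y, z] == 0:
                        votes[x, y, z] = ctr_major[m]
                        processed[x, y, z] = 1
                        fallback[x, y, z] = 1


def _run_fusion(
    subject: IntensityVolume,
    library: TemplateLibrary,
    roi: BinaryMask,
    config: FusionConfig,
    level: int,
    block_radius: int,
    block_spacing: int,
    bilateral: bool,
) -> VoteVolume:
    if len(library) == 0:
        raise ValueError("no templates supplied")
    if subject.shape != library.grid_shape or subject.shape != roi.shape:
        raise ValueError(
            f"subject {subject.shape}, library {library.grid_shape} and roi "
            f"{roi.shape} must share one grid"
        )
    if roi.count() == 0:
        raise ValueError("ROI is empty")
    centers = block_center_grid(subject.shape, block_spacing, block_radius, roi.data)
    img = np.ascontiguousarray(subject.data, dtype=np.float64)
    tmpl = np.ascontiguousarray(library.intensity_stack(), dtype=np.float64)
    labs = np.ascontiguousarray(library.mask_stack(), dtype=np.uint8)
    num = np.zeros(subject.shape, dtype=np.float64)
    mass = np.zeros(subject.shape, dtype=np.float64)
    ctr_zero = np.zeros(len(centers), dtype=np.uint8)
    ctr_major = np.zeros(len(centers), dtype=np.uint8)
    vsx, vsy, vsz = subject.voxel_size_mm
    _fuse_kernel(
        img,
        tmpl,
        labs,
        centers,
        int(config.patch_radius[level]),
        int(config.search_radius[level]),
        int(block_radius),
        float(config.lambda_h),
        float(config.epsilon_h),
        float(config.sigma_d_mm),
        float(config.ss_threshold),
        float(vsx),
        float(vsy),
        float(vsz),
        bool(bilateral),
        num,
        mass,
        ctr_zero,
        ctr_major,
    )
    votes = np.zeros(subject.shape, dtype=np.float64)
    processed = (mass > 0).astype(np.uint8)
    np.divide(num, mass, out=votes, where=mass > 0)
    fallback = np.zeros(subject.shape, dtype=np.uint8)
    if ctr_zero.any():
        _apply_fallback(
            centers, ctr_zero, ctr_major, int(block_radius), mass, votes, processed,
            fallback,
        )
    return VoteVolume(votes, mass, processed, fallback)


def voxelwise_fusion(
    subject: IntensityVolume,
    library: TemplateLibrary,
    roi: BinaryMask,
    config: FusionConfig,
    level: int = -1,
    bilateral: bool = True,
) -> VoteVolume:
    """Voxelwise nonlocal label fusion over every ROI voxel.

    ``level`` indexes the per-level patch/search radii in ``config``
    (default: finest).  ``bilateral=False`` selects the classical
    intensity-only baseline weight.
    """
    return _run_fusion(
        subject, library, roi, config, level, block_radius=0, block_spacing=1,
        bilateral=bilateral,
    )


def blockwise_fusion(
    subject: IntensityVolume,
    library: TemplateLibrary,
    roi: BinaryMask,
    config: FusionConfig,
    level: int = -1,
    bilateral: bool = True,
) -> VoteVolume:
    """Blockwise overcomplete label fusion.

    One weight per candidate labels the candidate's whole block; votes are
    averaged over all covering blocks.  With ``block_radius=0`` and
    ``block_spacing=1`` this reduces exactly to :func:`voxelwise_fusion`.
    """
    return _run_fusion(
        subject,
        library,
        roi,
        config,
        level,
        block_radius=config.block_radius,
        block_spacing=config.block_spacing,
        bilateral=bilateral,
    )


def threshold_votes(votes: VoteVolume, vote_threshold: float = 0.5) -> BinaryMask:
    """Binarize a vote field: label 1 where v >= threshold (processed
    voxels only), 0 elsewhere."""
    out = np.zeros(votes.shape, dtype=np.uint8)
    out[(votes.processed > 0) & (votes.votes >= vote_threshold)] = 1
    return BinaryMask(out)
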