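"""Synthetic 3-tissue head phantoms with known intracranial masks.

A phantom is a nest of ellipsoids — background, skull shell, then the
intracranial compartment as a CSF layer, a grey-matter shell, a
white-matter core and CSF-filled ventricles — on a 1 mm isotropic grid.
Intensities sit on the normalized scale (CSF 50 / GM 150 / WM 250, skull
40, background 10) with optional additive Gaussian noise.  Inter-subject
anatomical variability is emulated by a smooth random displacement field
(a sum of low-frequency sinusoids with seeded phases, amplitude-capped)
applied identically to labels and intensities, so every phantom carries an
exact ground-truth intracranial mask.

Tissue labels: 0 background, 1 skull, 2 CSF, 3 GM, 4 WM.  The
intracranial mask is the union of CSF/GM/WM (ventricles included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, IntensityVolume, TemplateLibrary, validate_library

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "make_library",
    "LABEL_BACKGROUND",
    "LABEL_SKULL",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
]

LABEL_BACKGROUND, LABEL_SKULL, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and perturbations of one synthetic head.

    Semi-axes are in voxels and must nest strictly:
    skull > intracranial (outer CSF) > GM > WM > ventricle.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    skull_axes: tuple[float, float, float] = (27.0, 25.0, 24.0)
    ic_axes: tuple[float, float, float] = (24.0, 22.0, 21.0)
    gm_axes: tuple[float, float, float] = (21.0, 19.0, 18.0)
    wm_axes: tuple[float, float, float] = (16.0, 14.0, 13.0)
    ventricle_axes: tuple[float, float, float] = (5.0, 4.0, 3.0)
    tissue_means: dict[int, float] = field(
        default_factory=lambda: {
            LABEL_BACKGROUND: 10.0,
            LABEL_SKULL: 40.0,
            LABEL_CSF: 50.0,
            LABEL_GM: 150.0,
            LABEL_WM: 250.0,
        }
    )
    noise_sd: float = 5.0
    deformation_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        nests = (self.skull_axes, self.ic_axes, self.gm_axes, self.wm_axes,
                 self.ventricle_axes)
        for outer, inner in zip(nests, nests[1:]):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError(
                    f"shells must nest strictly: {outer} vs {inner}"
                )
        margin = [s / 2 - a for s, a in zip(self.shape, self.skull_axes)]
        if min(margin) < 2:
            raise ValueError(
                "grid too small: outer shell needs a 2-voxel margin, "
                f"shape {self.shape} vs skull axes {self.skull_axes}"
            )
        if self.noise_sd < 0 or self.deformation_amplitude < 0:
            raise ValueError("noise_sd and deformation_amplitude must be >= 0")

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((s - 1) / 2.0 for s in self.shape)


def _ellipsoid(grid: tuple[np.ndarray, ...], center, axes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center, axes))
    return q <= 1.0


def _base_labels(spec: PhantomSpec) -> np.ndarray:
    grid = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in spec.shape),
                       indexing="ij")
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[_ellipsoid(grid, spec.center, spec.skull_axes)] = LABEL_SKULL
    labels[_ellipsoid(grid, spec.center, spec.ic_axes)] = LABEL_CSF
    labels[_ellipsoid(grid, spec.center, spec.gm_axes)] = LABEL_GM
    labels[_ellipsoid(grid, spec.center, spec.wm_axes)] = LABEL_WM
    labels[_ellipsoid(grid, spec.center, spec.ventricle_axes)] = LABEL_CSF
    return labels


def _displacement(spec: PhantomSpec, rng: np.random.Generator) -> list[np.ndarray]:
    """Smooth displacement per axis: amplitude-capped sum of 3 low-frequency
    sinusoids with random orientations and phases."""
    coords = np.meshgrid(
        *(np.arange(s, dtype=np.float64) / s for s in spec.shape), indexing="ij"
    )
    fields = []
    for _ in range(3):
        acc = np.zeros(spec.shape, dtype=np.float64)
        for _ in range(3):
            freq = rng.integers(1, 3, size=3)  # 1-2 cycles per axis
            phase = rng.uniform(0, 2 * np.pi)
            weights = rng.uniform(-1, 1, size=3)
            arg = phase
            for c, f, w in zip(coords, freq, weights):
                arg = arg + 2 * np.pi * f * w * c
            acc += np.sin(arg)
        fields.append(spec.deformation_amplitude * acc / 3.0)
    return fields


def make_phantom(
    spec: PhantomSpec,
) -> tuple[IntensityVolume, BinaryMask, np.ndarray]:
    """Generate one phantom: intensity volume, intracranial mask and the
    full tissue label volume.  Fully reproducible from (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    labels = _base_labels(spec)
    if spec.deformation_amplitude > 0:
        disp = _displacement(spec, rng)
        coords = np.meshgrid(
            *(np.arange(s, dtype=np.float64) for s in spec.shape), indexing="ij"
        )
        sample_at = [c + d for c, d in zip(coords, disp)]
        labels = ndimage.map_coordinates(
            labels, sample_at, order=0, mode="nearest"
        ).astype(np.uint8)
    lut = np.array(
        [spec.tissue_means[k] for k in range(5)], dtype=np.float64
    )
    intensity = lut[labels]
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    ic = np.isin(labels, (LABEL_CSF, LABEL_GM, LABEL_WM)).astype(np.uint8)
    return (
        IntensityVolume(intensity, spec.voxel_size_mm),
        BinaryMask(ic, spec.voxel_size_mm),
        labels,
    )


def make_library(
    base: PhantomSpec,
    n: int,
    deformation_amplitude: float | None = None,
    intensity_jitter_sd: float = 5.0,
    seed: int | None = None,
) -> TemplateLibrary:
    """Library of ``n`` independently perturbed phantoms.

    Each template gets its own seeded shape deformation (amplitude from
    ``deformation_amplitude``, defaulting to the base spec's) and a global
    jitter of the three intracranial tissue means (sd
    ``intensity_jitter_sd`` normalized units), emulating residual
    inter-subject intensity differences after normalization.  The paired
    masks are the exact ground truths.
    """
    if n < 1:
        raise ValueError("library size must be >= 1")
    if deformation_amplitude is None:
        deformation_amplitude = base.deformation_amplitude
    root = np.random.default_rng(base.seed if seed is None else seed)
    pairs = []
    for i in range(n):
        child_seed = int(root.integers(0, 2**31 - 1))
        jit = np.random.default_rng(child_seed)
        means = dict(base.tissue_means)
        if intensity_jitter_sd > 0:
            for lab in (LABEL_CSF, LABEL_GM, LABEL_WM):
                means[lab] = float(
                    means[lab] + jit.normal(0.0, intensity_jitter_sd)
                )
        spec_i = replace(
            base,
            tissue_means=means,
            deformation_amplitude=float(deformation_amplitude),
            seed=child_seed,
        )
        vol, msk, _ = make_phantom(spec_i)
        pairs.append((vol, msk))
    return validate_library(TemplateLibrary(pairs))
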