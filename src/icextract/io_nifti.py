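"""NIfTI-1 volume/mask I/O and on-disk template-library manifests.

Orientation metadata (the affine) is preserved verbatim but never used for
resampling: inputs are expected to be pre-registered to a common grid, and
any grid-shape mismatch is an error rather than a silent resample.
Intensities are written as 32-bit float, masks as unsigned 8-bit so label
round trips are exact.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BinaryMask, IntensityVolume, TemplateLibrary, validate_library

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "LibraryManifest",
    "load_manifest",
    "load_library",
    "save_library",
]


class VolumeIOError(IOError):
    """Raised when a NIfTI file cannot be read as a valid 3D volume."""


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, img.affine


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a NIfTI-1 file (optionally gzipped) as an intensity volume."""
    data, zooms, affine = _load_nifti(path)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeIOError(f"{path}: volume contains non-finite values")
    return IntensityVolume(data, zooms, affine)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI-1 file as a binary mask (values must be exactly 0/1)."""
    data, zooms, affine = _load_nifti(path)
    values = np.unique(data)
    if not np.isin(values, (0, 1)).all():
        raise VolumeIOError(f"{path}: mask values are not 0/1 (found {values[:10]})")
    return BinaryMask(data.astype(np.uint8), zooms, affine)


def _reference_affine(reference: IntensityVolume | BinaryMask) -> np.ndarray:
    if reference.affine is not None:
        return np.asarray(reference.affine)
    return np.diag(list(reference.voxel_size_mm) + [1.0])


def write_volume(
    volume: IntensityVolume,
    path: str | Path,
    reference: IntensityVolume | BinaryMask | None = None,
) -> None:
    """Write an intensity volume as float32 NIfTI with the reference geometry."""
    ref = reference if reference is not None else volume
    img = nib.Nifti1Image(volume.data.astype(np.float32), _reference_affine(ref))
    img.header.set_zooms(ref.voxel_size_mm)
    nib.save(img, str(path))


def write_mask(
    mask: BinaryMask,
    reference: IntensityVolume | BinaryMask,
    path: str | Path,
) -> None:
    """Write a binary mask as uint8 NIfTI aligned with ``reference``."""
    if mask.shape != reference.shape:
        raise VolumeIOError(
            f"mask shape {mask.shape} does not match reference {reference.shape}"
        )
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _reference_affine(reference))
    img.header.set_zooms(reference.voxel_size_mm)
    nib.save(img, str(path))


@dataclass
class LibraryManifest:
    """Paths of the (intensity, mask) pairs making up a template library.

    Relative paths are resolved against ``root`` (the manifest's directory
    when loaded from disk).
    """

    entries: list[tuple[str, str, str]]  # (intensity path, mask path, tag)
    root: Path = field(default_factory=Path)

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.root / path


def load_manifest(path: str | Path) -> LibraryManifest:
    """Load a manifest from JSON ({"entries": [{intensity, mask, tag?}]})
    or CSV (columns intensity, mask[, tag])."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such manifest: {path}")
    entries: list[tuple[str, str, str]] = []
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        rows = doc["entries"] if isinstance(doc, dict) else doc
        for i, row in enumerate(rows):
            entries.append(
                (row["intensity"], row["mask"], str(row.get("tag", f"entry{i}")))
            )
    else:
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                entries.append(
                    (row["intensity"], row["mask"], row.get("tag") or f"entry{i}")
                )
    return LibraryManifest(entries, root=path.parent)


def load_library(manifest: LibraryManifest | str | Path) -> TemplateLibrary:
    """Load and validate the template library a manifest describes.

    Any failure is reported with the offending entry's tag.
    """
    if not isinstance(manifest, LibraryManifest):
        manifest = load_manifest(manifest)
    if not manifest.entries:
        raise VolumeIOError("manifest lists no library entries")
    pairs = []
    for ipath, mpath, tag in manifest.entries:
        try:
            vol = read_volume(manifest.resolve(ipath))
            msk = read_mask(manifest.resolve(mpath))
        except (VolumeIOError, ValueError) as exc:
            raise VolumeIOError(f"library entry '{tag}': {exc}") from exc
        pairs.append((vol, msk))
    return validate_library(TemplateLibrary(pairs))


def save_library(
    library: TemplateLibrary,
    out_dir: str | Path,
    prefix: str = "template",
) -> Path:
    """Write every pair of a library plus a JSON manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (vol, msk) in enumerate(library):
        iname = f"{prefix}_{i:03d}.nii.gz"
        mname = f"{prefix}_{i:03d}_mask.nii.gz"
        write_volume(vol, out_dir / iname)
        write_mask(msk, vol, out_dir / mname)
        rows.append({"intensity": iname, "mask": mname, "tag": f"{prefix}_{i:03d}"})
    manifest_path = out_dir / "library.json"
    manifest_path.write_text(json.dumps({"entries": rows}, indent=2))
    return manifest_path
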