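"""Volume and structure-set file I/O.

Canonical interchange formats are NRRD / NIfTI-1 for scalar volumes and a
JSON manifest plus per-ROI uint8 NRRD masks for structure sets.  A
best-effort DICOM import (RTDOSE grids and RTSTRUCT contour sets on a
single frame of reference) lives in :mod:`sctdosim.dicom`.

Axis convention: in-memory arrays are indexed (x, y, z) in LPS; SimpleITK
stores (z, y, x), so arrays are transposed on the way in and out.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import HeaderError, VolumeFormatError
from .geometry import GridSpec, ImageVolume
from .structures import StructureSet

_SUPPORTED = (".nrrd", ".nii", ".nii.gz")


def _check_suffix(path: Path):
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED):
        raise VolumeFormatError(f"unsupported volume format: {path.name} (use NRRD or NIfTI)")


def read_volume(path, unit: str) -> ImageVolume:
    """Read an NRRD or NIfTI volume and tag it with a physical unit.

    Geometry (origin, spacing) is taken bit-exactly from the header.  The
    image must be axis-aligned in LPS (identity direction cosines).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as e:  # pragma: no cover - exercised via corrupt files
        raise VolumeFormatError(f"unreadable volume {path}: {e}") from e
    if img.GetDimension() != 3:
        raise HeaderError(f"{path}: expected a 3D volume, got {img.GetDimension()}D")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise HeaderError(f"{path}: non-positive spacing {spacing}")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise HeaderError(f"{path}: only axis-aligned LPS volumes are supported")
    values = sitk.GetArrayFromImage(img).T  # (z,y,x) -> (x,y,z)
    grid = GridSpec(values.shape, img.GetOrigin(), spacing)
    return ImageVolume(values, grid, unit)


def write_volume(vol: ImageVolume, path) -> Path:
    """Write a volume as NRRD or NIfTI (chosen by extension)."""
    path = Path(path)
    _check_suffix(path)
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def write_structure_set(structures: StructureSet, directory, manifest_name="structures.json") -> Path:
    """Write a structure set as a JSON manifest + uint8 NRRD masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rois = []
    for roi in structures.rois:
        mask_file = f"mask_{roi.name}.nrrd"
        write_volume(
            ImageVolume(roi.mask, structures.grid, "arbitrary-MR"),
            directory / mask_file,
        )
        rois.append({"name": roi.name, "role": roi.role, "mask_file": mask_file})
    manifest = {
        "geometry": {
            "shape": list(structures.grid.shape),
            "origin": list(structures.grid.origin),
            "spacing": list(structures.grid.spacing),
        },
        "rois": rois,
    }
    out = directory / manifest_name
    out.write_text(json.dumps(manifest, indent=2))
    return out


def read_structure_set(manifest_path) -> StructureSet:
    """Read a structure set from a JSON manifest written by
    :func:`write_structure_set`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    geom = manifest["geometry"]
    grid = GridSpec(tuple(geom["shape"]), tuple(geom["origin"]), tuple(geom["spacing"]))
    ss = StructureSet(grid)
    for entry in manifest["rois"]:
        vol = read_volume(manifest_path.parent / entry["mask_file"], "arbitrary-MR")
        if not vol.grid.same_geometry(grid, tol=1e-6):
            raise HeaderError(f"mask {entry['name']!r} geometry differs from manifest")
        ss.add(entry["name"], entry["role"], vol.values.astype(bool))
    return ss
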