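"""Best-effort DICOM import: RTDOSE grids and RTSTRUCT contour sets.

Supports the common axial, single-frame-of-reference case with identity
orientation.  Contours are rasterized slice by slice with even-odd fill
(XOR across stacked polygons), so ring structures with holes come out
hollow.  DICOM *writing* is out of scope.
"""

from __future__ import annotations

import numpy as np
import pydicom

from .errors import HeaderError
from .geometry import GridSpec, ImageVolume
from .structures import StructureSet


def read_rtdose(path) -> ImageVolume:
    """Read a DICOM RTDOSE file into a Gy-tagged volume."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise HeaderError(f"{path}: not an RTDOSE file")
    arr = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)  # (z, y, x)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing = y, col = x
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) == 0 or not np.allclose(dz, dz[0], atol=1e-6):
        raise HeaderError(f"{path}: non-uniform or missing frame offsets")
    grid = GridSpec(arr.T.shape, origin, (dx, dy, float(dz[0])))
    return ImageVolume(arr.T, grid, "Gy")


def read_rtstruct(path, reference: GridSpec, roles: dict[str, str] | None = None) -> StructureSet:
    """Rasterize an RTSTRUCT onto a reference grid.

    Parameters
    ----------
    reference
        Grid the masks are rasterized on (normally the planning CT grid).
    roles
        Optional ROI-name -> role mapping; unmapped ROIs default to "oar".
    """
    from skimage.draw import polygon as draw_polygon

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise HeaderError(f"{path}: not an RTSTRUCT file")
    roles = roles or {}
    names = {
        int(item.ROINumber): str(item.ROIName) for item in ds.StructureSetROISequence
    }
    ss = StructureSet(reference)
    nx, ny, nz = reference.shape
    for roi_contour in ds.ROIContourSequence:
        name = names.get(int(roi_contour.ReferencedROINumber), "unknown")
        mask = np.zeros(reference.shape, dtype=bool)
        for contour in getattr(roi_contour, "ContourSequence", []):
            pts = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            idx = reference.world_to_index(pts)
            k = int(round(float(np.mean(idx[:, 2]))))
            if not 0 <= k < nz:
                continue
            rr, cc = draw_polygon(idx[:, 0], idx[:, 1], shape=(nx, ny))
            plane = np.zeros((nx, ny), dtype=bool)
            plane[rr, cc] = True
            mask[:, :, k] ^= plane  # even-odd fill across nested contours
        ss.add(name, roles.get(name, "oar"), mask)
    return ss
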