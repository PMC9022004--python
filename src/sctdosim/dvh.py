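"""Dose-volume-histogram metrics and point-dose comparison.

Dx% is the dose level such that exactly x% of the ROI volume receives at
least that dose, computed from the sorted voxel doses with linear
interpolation between order statistics; D1cc is the dose exceeded by
exactly 1 cm^3 of the ROI (interpolated the same way); V100% is the
percentage of the ROI receiving at least its prescription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose import DoseGrid
from .errors import InputError, UsageError
from .geometry import ImageVolume
from .structures import StructureSet


@dataclass
class DVHMetrics:
    """Per-ROI DVH metric table (Gy except V100% in percent)."""

    table: pd.DataFrame

    def metric(self, roi: str, name: str) -> float:
        row = self.table.loc[self.table["roi"] == roi]
        if row.empty:
            raise KeyError(roi)
        return float(row[name].iloc[0])


def _as_volume(dose) -> ImageVolume:
    return dose.dose if isinstance(dose, DoseGrid) else dose


def dose_at_coverage(sorted_desc: np.ndarray, fraction: float) -> float:
    """Dose level at a cumulative volume fraction.

    ``sorted_desc`` are the ROI voxel doses sorted descending; the k-th
    value (1-based) covers k/n of the volume.  The level at an arbitrary
    fraction interpolates linearly between adjacent order statistics and
    clamps to the hottest voxel below 1/n.
    """
    n = sorted_desc.size
    k = fraction * n  # target cumulative count
    if k <= 1.0:
        return float(sorted_desc[0])
    if k >= n:
        return float(sorted_desc[-1])
    lo = int(np.floor(k))
    f = k - lo
    return float(sorted_desc[lo - 1] * (1 - f) + sorted_desc[lo] * f)


def dvh_metrics(
    dose,
    structures: StructureSet,
    prescriptions_gy: dict[str, float] | None = None,
    rois: list[str] | None = None,
) -> DVHMetrics:
    """Compute D_mean, D_max, D98%, D2%, D1cc and V100% per ROI.

    ROIs smaller than 1 cm^3 report D1cc as D_max with ``d1cc_flag``
    set.  V100% is NaN for ROIs without a prescription.
    """
    vol = _as_volume(dose)
    if tuple(vol.shape) != structures.grid.shape:
        raise UsageError("dose and structures are on different grids")
    prescriptions_gy = prescriptions_gy or {}
    voxel_cc = structures.grid.voxel_volume_cc
    rows = []
    for roi in structures.rois:
        if rois is not None and roi.name not in rois:
            continue
        n = roi.voxel_count
        if n == 0:
            raise InputError(f"ROI {roi.name!r} is empty")
        doses = np.sort(vol.values[roi.mask])[::-1]
        d_mean = float(doses.mean())
        d_max = float(doses[0])
        d98 = dose_at_coverage(doses, 0.98)
        d2 = dose_at_coverage(doses, 0.02)
        roi_cc = n * voxel_cc
        if roi_cc < 1.0:
            d1cc, flag = d_max, True
        else:
            d1cc, flag = dose_at_coverage(doses, 1.0 / roi_cc), False
        rx = prescriptions_gy.get(roi.name)
        v100 = 100.0 * float((doses >= rx).mean()) if rx else np.nan
        rows.append({
            "roi": roi.name, "role": roi.role, "n_voxels": n,
            "d_mean": d_mean, "d_max": d_max, "d98": d98, "d2": d2,
            "d1cc": d1cc, "d1cc_flag": flag, "v100": v100,
        })
    return DVHMetrics(pd.DataFrame(rows))


def point_dose_difference(
    reference,
    evaluated,
    structures: StructureSet,
    roi: str = "ptv_nx",
) -> float:
    """Percent dose difference at the ROI center.

    The point is the ROI centroid snapped to the nearest in-ROI voxel
    center (so C-shaped ROIs still sample inside the mask); the
    difference is 100 * (D_eval - D_ref) / D_ref at that point.
    """
    from .dose import snap_to_roi_voxel

    ref = _as_volume(reference)
    ev = _as_volume(evaluated)
    if structures[roi].voxel_count == 0:
        raise InputError(f"ROI {roi!r} is empty")
    point = snap_to_roi_voxel(structures, roi)
    idx = ref.grid.world_to_index(point).reshape(3, 1)
    d_ref = float(ndimage.map_coordinates(ref.values, idx, order=1)[0])
    d_ev = float(ndimage.map_coordinates(ev.values, ev.grid.world_to_index(point).reshape(3, 1), order=1)[0])
    if d_ref == 0.0:
        raise InputError("reference dose at the comparison point is zero")
    return 100.0 * (d_ev - d_ref) / d_ref
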