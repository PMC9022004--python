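"""HU -> relative electron density calibration and density segmentation.

Covers three jobs on the planning CT: (1) converting Hounsfield units to
relative electron density (rED, water = 1) through a piecewise-linear
calibration curve, (2) threshold segmentation of bone (HU > 250) and
internal air (HU < -300) with deterministic morphological cleanup in
place of manual contour editing, and (3) per-ROI rED statistics that feed
the bulk-assignment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, InputError, UsageError
from .geometry import ImageVolume
from .structures import StructureSet

#: Default calibration nodes (HU, rED): air, lung-like, water, spongy
#: bone onset, dense bone.  Scanner-specific curves can replace this; all
#: downstream behavior is curve-agnostic.
DEFAULT_CURVE_NODES = (
    (-1000.0, 0.001),
    (-300.0, 0.71),
    (0.0, 1.0),
    (250.0, 1.12),
    (1200.0, 1.72),
)


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise-linear HU -> rED map, clamped at both end nodes."""

    nodes: tuple = DEFAULT_CURVE_NODES

    def __post_init__(self):
        nodes = tuple((float(h), float(r)) for h, r in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(nodes) < 2:
            raise ConfigError("calibration curve needs at least 2 nodes")
        hu = np.array([n[0] for n in nodes])
        red = np.array([n[1] for n in nodes])
        if np.any(np.diff(hu) <= 0):
            raise ConfigError("calibration HU nodes must be strictly increasing")
        if np.any(np.diff(red) < 0):
            raise ConfigError("calibration rED nodes must be non-decreasing")
        if np.any(red < 0):
            raise ConfigError("calibration rED values must be non-negative")
        if not np.any(np.isclose(hu, 0.0) & np.isclose(red, 1.0)):
            raise ConfigError("calibration curve must contain the water node (0 HU, rED 1)")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        h = np.array([n[0] for n in self.nodes])
        r = np.array([n[1] for n in self.nodes])
        return np.interp(np.asarray(hu, dtype=float), h, r)

    @staticmethod
    def from_pairs(pairs) -> "CalibrationCurve":
        return CalibrationCurve(tuple((float(h), float(r)) for h, r in pairs))


@dataclass(frozen=True)
class ThresholdConfig:
    """Bone/air threshold segmentation parameters.

    Bone is ``HU > bone_hu`` and air is ``HU < air_hu``, both restricted
    to the body; morphological closing and small-component removal stand
    in for the manual contour editing a physicist would apply.
    """

    bone_hu: float = 250.0
    air_hu: float = -300.0
    min_component_cc: float = 0.5
    closing_radius_voxels: int = 1

    def __post_init__(self):
        if self.air_hu >= self.bone_hu:
            raise ConfigError("air threshold must be below the bone threshold")


@dataclass
class ROIDensitySummary:
    """Per-ROI density statistics (voxel count, mean HU, mean/sd rED)."""

    table: pd.DataFrame

    def mean_red(self, name: str) -> float:
        row = self.table.loc[self.table["roi"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["mean_red"].iloc[0])

    def roles(self) -> dict[str, str]:
        return dict(zip(self.table["roi"], self.table["role"]))

    @property
    def names(self) -> list[str]:
        return list(self.table["roi"])

    def empty_rois(self) -> list[str]:
        return list(self.table.loc[self.table["n_voxels"] == 0, "roi"])

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def hu_to_red(vol: ImageVolume, curve: CalibrationCurve | None = None) -> ImageVolume:
    """Convert a HU volume to rED through the calibration curve.

    Voxelwise piecewise-linear interpolation, clamped to the end nodes;
    monotone non-decreasing in HU by construction.
    """
    if vol.unit != "HU":
        raise UsageError(f"hu_to_red expects a HU volume, got {vol.unit!r}")
    curve = curve or CalibrationCurve()
    return vol.with_values(curve(vol.values), unit="rED")


def _cleanup(mask: np.ndarray, cfg: ThresholdConfig, voxel_cc: float) -> np.ndarray:
    if cfg.closing_radius_voxels > 0 and mask.any():
        r = cfg.closing_radius_voxels
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_closing(mask, structure=structure, iterations=r)
    if cfg.min_component_cc > 0 and mask.any():
        labels, n = ndimage.label(mask)
        if n:
            counts = np.bincount(labels.ravel())
            keep = counts * voxel_cc >= cfg.min_component_cc
            keep[0] = False
            mask = keep[labels]
    return mask


def segment_bone_air(
    ct: ImageVolume,
    body: np.ndarray,
    cfg: ThresholdConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-segment bone and internal air on the planning CT.

    The body mask excludes exterior air (couch, background); the returned
    masks are disjoint, with bone taking precedence on (pathological)
    overlap after morphology.
    """
    if ct.unit != "HU":
        raise UsageError("segment_bone_air expects a HU volume")
    body = np.asarray(body, dtype=bool)
    if not body.any():
        raise InputError("body mask is empty")
    cfg = cfg or ThresholdConfig()
    voxel_cc = ct.grid.voxel_volume_cc
    bone = _cleanup((ct.values > cfg.bone_hu) & body, cfg, voxel_cc) & body
    air = _cleanup((ct.values < cfg.air_hu) & body, cfg, voxel_cc) & body
    air &= ~bone
    return bone, air


def summarize_roi_red(
    red: ImageVolume,
    structures: StructureSet,
    hu: ImageVolume | None = None,
) -> ROIDensitySummary:
    """Per-ROI rED statistics (and mean HU when the HU volume is given).

    Empty ROIs are reported with count 0 and NaN statistics rather than
    dropped, so callers can flag them.
    """
    if red.unit != "rED":
        raise UsageError("summarize_roi_red expects an rED volume")
    if tuple(red.shape) != structures.grid.shape:
        raise UsageError("rED volume and structure set are on different grids")
    rows = []
    for roi in structures.rois:
        n = roi.voxel_count
        if n == 0:
            rows.append({"roi": roi.name, "role": roi.role, "n_voxels": 0,
                         "mean_hu": np.nan, "mean_red": np.nan, "sd_red": np.nan})
            continue
        vals = red.values[roi.mask]
        rows.append({
            "roi": roi.name,
            "role": roi.role,
            "n_voxels": n,
            "mean_hu": float(hu.values[roi.mask].mean()) if hu is not None else np.nan,
            "mean_red": float(vals.mean()),
            "sd_red": float(vals.std(ddof=1)) if n > 1 else 0.0,
        })
    return ROIDensitySummary(pd.DataFrame(rows))
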