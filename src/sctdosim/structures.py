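"""Structure sets: named binary ROI masks on a reference grid.

Each ROI carries a *role* used by downstream stages: ``body`` delimits the
patient, ``bone`` / ``air`` are the density-override regions, ``target``
and ``oar`` drive the dosimetric endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, UsageError
from .geometry import GridSpec, ImageVolume, RigidTransform, resample_to_grid

ROLES = ("target", "oar", "bone", "air", "body")


@dataclass
class ROI:
    name: str
    role: str
    mask: np.ndarray

    def __post_init__(self):
        if self.role not in ROLES:
            raise UsageError(f"unknown ROI role {self.role!r}; expected one of {ROLES}")
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def centroid_index(self) -> np.ndarray:
        """Center of mass of the mask in continuous index coordinates."""
        if self.voxel_count == 0:
            raise InputError(f"ROI {self.name!r} is empty")
        idx = np.argwhere(self.mask)
        return idx.mean(axis=0)


@dataclass
class StructureSet:
    """Ordered collection of ROIs sharing one reference grid."""

    grid: GridSpec
    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self):
        for roi in self.rois:
            self._check(roi)

    def _check(self, roi: ROI):
        if tuple(roi.mask.shape) != self.grid.shape:
            raise UsageError(
                f"mask {roi.name!r} shape {roi.mask.shape} != grid {self.grid.shape}"
            )

    def add(self, name: str, role: str, mask: np.ndarray) -> ROI:
        roi = ROI(name, role, mask)
        self._check(roi)
        if name in self.names():
            raise UsageError(f"duplicate ROI name {name!r}")
        self.rois.append(roi)
        return roi

    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def __contains__(self, name: str) -> bool:
        return name in self.names()

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_role(self, role: str) -> list[ROI]:
        return [r for r in self.rois if r.role == role]

    @property
    def body(self) -> ROI:
        bodies = self.by_role("body")
        if not bodies:
            raise InputError("structure set has no body ROI")
        return bodies[0]

    def validate(self):
        """Check structural invariants.

        The body mask must be non-empty, and every non-body mask must lie
        inside the body (air cavities are internal, so air ROIs count as
        part of the patient extent here).
        """
        body = self.body
        if body.voxel_count == 0:
            raise InputError("body mask is empty")
        allowed = body.mask.copy()
        for air in self.by_role("air"):
            allowed |= air.mask
        for roi in self.rois:
            if roi.role == "body":
                continue
            if np.any(roi.mask & ~allowed):
                raise InputError(f"ROI {roi.name!r} extends outside the body")

    def roi_centroid_world(self, name: str) -> np.ndarray:
        return self.grid.index_to_world(self[name].centroid_index())

    def propagate(self, target: GridSpec, transform: RigidTransform) -> "StructureSet":
        """Propagate all masks to a target grid through a rigid transform.

        Masks use nearest-neighbor resampling, the standard TPS behavior
        for contour transfer between co-registered image frames.
        """
        out = StructureSet(target)
        for roi in self.rois:
            vol = ImageVolume(roi.mask, self.grid, "arbitrary-MR")
            moved = resample_to_grid(vol, target, transform, mode="nearest")
            out.add(roi.name, roi.role, moved.values)
        return out
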