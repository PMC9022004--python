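"""Volume and geometry data model shared by every pipeline stage.

All volumes live on axis-aligned regular grids in the patient LPS frame
(+x left, +y posterior, +z superior).  Voxel indices are 0-based and the
world coordinate of a voxel is the position of its *center*:

    world = origin + index * spacing        (per axis)

Arrays are indexed ``values[i, j, k]`` with axis order (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import ndimage

from .errors import UsageError

#: Recognized physical unit tags.
UNITS = ("HU", "rED", "Gy", "arbitrary-MR")

#: Fill value used when resampling pulls from outside the source support.
#: Out-of-body space behaves as air (HU -1000 / rED 0.001); dose vanishes.
FILL_VALUES = {"HU": -1000.0, "rED": 0.001, "Gy": 0.0, "arbitrary-MR": 0.0}


@dataclass(frozen=True)
class GridSpec:
    """Description of a regular 3D sampling grid (shape, origin, spacing)."""

    shape: tuple[int, int, int]
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise UsageError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise UsageError(f"grid spacing must be strictly positive, got {self.spacing}")

    # -- coordinate transforms -------------------------------------------------

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices to world mm, shape (..., 3)."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map world mm points to continuous voxel indices, shape (..., 3).

        Out-of-grid points simply return out-of-range indices.
        """
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of the voxel centers."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class ImageVolume:
    """A 3D scalar field on a :class:`GridSpec` with a physical unit tag.

    The unit tag drives validation (rED maps must be non-negative) and the
    fill value used when the volume is resampled beyond its support.
    """

    values: np.ndarray
    grid: GridSpec
    unit: str
    frame: str = field(default="LPS")

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise UsageError("ImageVolume requires a 3D array")
        if tuple(self.values.shape) != self.grid.shape:
            raise UsageError(
                f"array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.unit not in UNITS:
            raise UsageError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.frame != "LPS":
            raise UsageError("only the LPS frame is supported")
        if self.unit == "rED" and np.any(self.values < 0):
            raise UsageError("rED volumes must be non-negative everywhere")

    # convenience accessors ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def fill_value(self) -> float:
        return FILL_VALUES[self.unit]

    def world_to_index(self, point) -> np.ndarray:
        return self.grid.world_to_index(point)

    def index_to_world(self, index) -> np.ndarray:
        return self.grid.index_to_world(index)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ImageVolume":
        """New volume on the same grid with different values (and unit)."""
        return ImageVolume(values, self.grid, unit or self.unit)

    def sample(self, points: np.ndarray, mode: str = "linear") -> np.ndarray:
        """Interpolate the volume at world points, shape (N, 3) -> (N,)."""
        idx = self.grid.world_to_index(points)
        order = {"linear": 1, "nearest": 0}[mode]
        return ndimage.map_coordinates(
            self.values.astype(float, copy=False),
            idx.T,
            order=order,
            mode="constant",
            cval=self.fill_value,
        )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in world (mm) coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise UsageError("rotation matrix is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise UsageError("rotation matrix must have determinant +1")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler_deg(
        angles_deg: Iterable[float], translation: Iterable[float] = (0, 0, 0)
    ) -> "RigidTransform":
        """Build from extrinsic rotations about x, then y, then z (degrees)."""
        ax, ay, az = np.deg2rad(list(angles_deg))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return RigidTransform(Rz @ Ry @ Rx, np.asarray(list(translation), dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def is_identity(self, tol: float = 1e-12) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=tol) and np.allclose(
            self.translation, 0.0, atol=tol
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def resample_to_grid(
    vol: ImageVolume,
    target: GridSpec,
    transform: RigidTransform | None = None,
    mode: str = "linear",
) -> ImageVolume:
    """Resample a volume onto a target grid through a rigid transform.

    ``transform`` maps *source-frame* world coordinates into the target
    frame (the forward motion of the object); each target voxel center is
    pulled back through its inverse and interpolated in the source volume.
    Points outside the source support take the unit's fill value.

    Boolean masks must use ``mode="nearest"`` and stay boolean.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if mode not in ("linear", "nearest"):
        raise UsageError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    is_mask = vol.values.dtype == bool
    if is_mask and mode == "linear":
        raise UsageError("linear interpolation of a boolean mask is not allowed; use mode='nearest'")

    # Identity fast path: bit-exact pass-through.
    if transform.is_identity() and vol.grid.same_geometry(target):
        return ImageVolume(vol.values.copy(), target, vol.unit)

    xs, ys, zs = target.world_coordinates()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    src_pts = transform.inverse().apply(pts)
    idx = vol.grid.world_to_index(src_pts)

    order = 1 if mode == "linear" else 0
    cval = 0.0 if is_mask else FILL_VALUES[vol.unit]
    out = ndimage.map_coordinates(
        vol.values.astype(np.uint8 if is_mask else np.float64),
        idx.T,
        order=order,
        mode="constant",
        cval=cval,
    ).reshape(target.shape)
    if is_mask:
        out = out.astype(bool)
    else:
        out = out.astype(float)
    return ImageVolume(out, target, vol.unit)
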