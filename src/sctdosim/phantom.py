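"""Seeded digital head-and-neck phantoms for end-to-end pipeline testing.

Each phantom is a paired pseudo-CT / pseudo-MRI with a structure set and a
*known* rigid offset between the two frames, emulating a nasopharyngeal
radiotherapy case: an ellipsoidal head with a cranial bone shell, internal
air cavities (nasopharynx and a sinus), four nested/adjacent planning
target volumes with the primary target abutting the nasopharyngeal cavity,
and a representative organ-at-risk subset (brainstem, spinal cord, both
parotids).

Densities are controlled through Hounsfield distributions per tissue
class.  The defaults place the cranium ROI mean relative electron density
inside the clinically reported 1.280-1.362 band and the air-cavity ROI
mean inside 0.196-0.327 after the default HU->rED calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PhantomSpecError
from .geometry import GridSpec, ImageVolume, RigidTransform, resample_to_grid
from .structures import StructureSet


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid primitive: center and semi-axes in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains_grid_points(self, grid: GridSpec) -> np.ndarray:
        """Boolean mask of grid voxel centers inside the ellipsoid."""
        xs, ys, zs = grid.world_coordinates()
        c, s = self.center, self.semi_axes
        u = ((xs - c[0]) / s[0]) ** 2
        v = ((ys - c[1]) / s[1]) ** 2
        w = ((zs - c[2]) / s[2]) ** 2
        return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        s = np.asarray(self.semi_axes)
        return c - s, c + s


@dataclass(frozen=True)
class TissueHU:
    """Gaussian Hounsfield-unit distribution of one tissue class."""

    mean: float
    sd: float


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic head phantom.

    All lengths in mm, all intensities in HU.  ``noise_sd`` is additive
    imaging noise applied on top of the per-tissue distributions inside
    the body.  ``mri_transform`` is the rigid motion carrying the CT frame
    into the MRI frame (the ground-truth registration).
    """

    shape: tuple[int, int, int] = (128, 128, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    head: Ellipsoid = field(default_factory=lambda: Ellipsoid((0, 0, 0), (75, 92, 88)))
    cranium_outer: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((0, 0, 0), (70, 86, 82))
    )
    cranium_thickness: float = 6.0
    cranium_z_min: float = -30.0
    cranium_hu: TissueHU = field(default_factory=lambda: TissueHU(570.0, 50.0))
    air_cavities: tuple[Ellipsoid, ...] = (
        Ellipsoid((0, -40, -40), (14, 11, 11)),  # nasopharynx (first = primary)
        Ellipsoid((0, -55, -5), (10, 9, 9)),  # sphenoid-sinus-like
    )
    air_hu: TissueHU = field(default_factory=lambda: TissueHU(-745.0, 60.0))
    soft_hu: TissueHU = field(default_factory=lambda: TissueHU(35.0, 12.0))
    targets: dict = field(
        default_factory=lambda: {
            "ptv_nx": Ellipsoid((0, -34, -40), (20, 17, 16)),
            "ptv_nd": Ellipsoid((42, -10, -55), (12, 12, 14)),
            "ptv_1": Ellipsoid((0, -30, -40), (30, 26, 24)),
            "ptv_2": Ellipsoid((0, -25, -40), (40, 36, 32)),
        }
    )
    oars: dict = field(
        default_factory=lambda: {
            "brainstem": Ellipsoid((0, 10, -15), (10, 12, 28)),
            "cord": Ellipsoid((0, 30, -60), (6, 6, 28)),
            "parotid_l": Ellipsoid((52, 8, -48), (10, 13, 14)),
            "parotid_r": Ellipsoid((-52, 8, -48), (10, 13, 14)),
        }
    )
    noise_sd: float = 10.0
    mri_transform: RigidTransform = field(
        default_factory=lambda: RigidTransform.from_euler_deg((0, 0, 2.0), (2.0, 2.0, 1.0))
    )
    seed: int = 0

    @property
    def grid(self) -> GridSpec:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(-(n - 1) * d / 2.0 for n, d in zip(shape, spacing))
        return GridSpec(shape, origin, spacing)

    def validate(self):
        grid = self.grid
        lo = np.asarray(grid.origin) - np.asarray(grid.spacing) / 2
        hi = lo + np.asarray(grid.shape) * np.asarray(grid.spacing)
        prims = [self.head, self.cranium_outer, *self.air_cavities]
        prims += list(self.targets.values()) + list(self.oars.values())
        for prim in prims:
            b_lo, b_hi = prim.bounds()
            if np.any(b_lo < lo) or np.any(b_hi > hi):
                raise PhantomSpecError(
                    f"primitive {prim} extends outside the grid [{lo}, {hi}]"
                )
        if self.cranium_thickness <= 0:
            raise PhantomSpecError("cranium thickness must be positive")
        for name in ("ptv_nx", "ptv_nd", "ptv_1", "ptv_2"):
            if name not in self.targets:
                raise PhantomSpecError(f"missing target {name!r}")


@dataclass
class Phantom:
    """A built phantom: images, structures and ground-truth densities."""

    ct: ImageVolume
    mri: ImageVolume
    structures: StructureSet
    truth: dict
    spec: PhantomSpec


def default_npc_spec(seed: int = 0) -> PhantomSpec:
    """The documented default nasopharyngeal phantom (2 mm isotropic,
    128 x 128 x 96 grid) with the density bands the analysis assumes."""
    spec = PhantomSpec(seed=int(seed))
    spec.validate()
    return spec


def _shell_mask(spec: PhantomSpec, grid: GridSpec) -> np.ndarray:
    outer = spec.cranium_outer
    inner = Ellipsoid(
        outer.center, tuple(s - spec.cranium_thickness for s in outer.semi_axes)
    )
    mask = outer.contains_grid_points(grid) & ~inner.contains_grid_points(grid)
    zs = grid.world_coordinates()[2]
    mask &= (zs >= spec.cranium_z_min)[None, None, :]
    return mask


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a :class:`PhantomSpec` into a deterministic phantom.

    The same spec (including seed) always yields bit-identical volumes.
    """
    spec.validate()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    body = spec.head.contains_grid_points(grid)
    cranium = _shell_mask(spec, grid) & body
    air = np.zeros(grid.shape, dtype=bool)
    for cav in spec.air_cavities:
        air |= cav.contains_grid_points(grid)
    air &= body
    air &= ~cranium  # cavities carved after bone; disjoint classes
    naso = spec.air_cavities[0].contains_grid_points(grid) & body

    # CT intensities: per-class Gaussians + global imaging noise in-body.
    ct = np.full(grid.shape, -1000.0)
    soft = body & ~cranium & ~air
    ct[soft] = rng.normal(spec.soft_hu.mean, spec.soft_hu.sd, int(soft.sum()))
    ct[cranium] = rng.normal(spec.cranium_hu.mean, spec.cranium_hu.sd, int(cranium.sum()))
    ct[air] = rng.normal(spec.air_hu.mean, spec.air_hu.sd, int(air.sum()))
    if spec.noise_sd > 0:
        ct[body] += rng.normal(0.0, spec.noise_sd, int(body.sum()))
    ct_vol = ImageVolume(ct, grid, "HU")

    structures = StructureSet(grid)
    structures.add("body", "body", body)
    structures.add("cranium", "bone", cranium)
    structures.add("air_cavity", "air", air)
    allowed = body | air
    for name, prim in spec.targets.items():
        structures.add(name, "target", prim.contains_grid_points(grid) & allowed)
    for name, prim in spec.oars.items():
        structures.add(name, "oar", prim.contains_grid_points(grid) & allowed)
    structures.validate()

    ptv_nx = structures["ptv_nx"].mask
    if not np.any(ptv_nx & naso):
        raise PhantomSpecError("ptv_nx does not intersect the nasopharyngeal cavity")
    if np.any(ptv_nx & ~structures["ptv_1"].mask) or np.any(
        structures["ptv_1"].mask & ~structures["ptv_2"].mask
    ):
        raise PhantomSpecError("targets are not nested (ptv_nx in ptv_1 in ptv_2)")

    # Pseudo-MRI: monotone nonlinear remap of tissue class moved into the
    # MRI frame by the known transform, plus independent Rician-like noise.
    # MR intensities are never used quantitatively downstream.
    intensity = np.full(grid.shape, 20.0)
    intensity[soft] = 800.0
    intensity[cranium] = 150.0
    intensity[air] = 50.0
    moved = resample_to_grid(
        ImageVolume(intensity, grid, "arbitrary-MR"), grid, spec.mri_transform, "linear"
    )
    mri = moved.values + rng.normal(0.0, 15.0, grid.shape)
    mri_vol = ImageVolume(np.abs(mri), grid, "arbitrary-MR")

    truth = {
        "cranium": {"mean_hu": spec.cranium_hu.mean, "assumed": False},
        "air_cavity": {"mean_hu": spec.air_hu.mean, "assumed": False},
        "body": {"mean_hu": None, "assumed": False},
    }
    # Soft-structure densities are water-adjacent assumptions: no
    # per-organ electron densities are clinically tabulated here.
    for name in list(spec.targets) + list(spec.oars):
        truth[name] = {"mean_hu": spec.soft_hu.mean, "assumed": True}

    return Phantom(ct_vol, mri_vol, structures, truth, spec)
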