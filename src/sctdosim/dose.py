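"""Simplified divergent-beam photon dose model.

This is a declared stand-in for a Monte Carlo engine: per beam, primary
dose is ``weight x inverse-square x buildup(d) x exp(-mu_eff d)`` along
diverging rays, where ``d`` is the radiological depth (line integral of
relative electron density), times an error-function lateral profile of a
rectangular field.  An optional magnetic-boundary perturbation emulates
the electron return effect (ERE) of a transverse 1.5 T field: wherever
the density drops sharply along a ray (tissue -> air), dose is moved from
the far (low-density) side back onto the near (dense) side, conserving
the integral along the ray.

The two mechanisms this engine models - sensitivity to rED line
integrals and a density-contrast boundary effect - are exactly the ones
that bulk density assignment perturbs; scatter, spectral hardening and
true charged-particle transport are deliberately absent.

Beam geometry: gantry angles rotate in the axial (x, y) plane about the
isocenter, 0 deg entering from anterior, 90 deg from the patient's left,
at a configurable source-axis distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import ConfigError, UsageError
from .geometry import ImageVolume
from .structures import StructureSet

DEFAULT_GANTRY_ANGLES = (0.0, 40.0, 80.0, 110.0, 160.0, 200.0, 250.0, 280.0, 320.0)
DEFAULT_PRESCRIPTIONS_GY = {"ptv_nx": 70.0, "ptv_nd": 70.0, "ptv_1": 60.0, "ptv_2": 54.0}


@dataclass(frozen=True)
class EREKernel:
    """Magnetic-boundary perturbation parameters.

    ``drop_threshold``: minimum along-ray rED drop that counts as a
    tissue-air interface.  ``enhancement``: fraction of downstream dose
    returned to the dense side for a unit density drop (scaled linearly
    with the actual drop).  ``range_mm``: exponential range of both the
    removal and the deposition lobes, an effective secondary-electron
    path length.
    """

    drop_threshold: float = 0.4
    enhancement: float = 0.3
    range_mm: float = 15.0

    def __post_init__(self):
        if not 0.0 <= self.enhancement < 1.0:
            raise ConfigError("ERE enhancement fraction must be in [0, 1)")
        if self.range_mm <= 0 or self.drop_threshold <= 0:
            raise ConfigError("ERE range and drop threshold must be positive")


@dataclass(frozen=True)
class BeamModel:
    """Engine parameters for a 7 MV FFF-like beam."""

    mu_eff_cm: float = 0.049
    buildup_cm: float = 1.5
    penumbra_sigma_mm: float = 3.0
    sad_mm: float = 1435.0
    b_on: bool = True
    ere: EREKernel = field(default_factory=EREKernel)

    def __post_init__(self):
        if self.mu_eff_cm <= 0 or self.penumbra_sigma_mm <= 0 or self.sad_mm <= 0:
            raise ConfigError("mu_eff, penumbra sigma and SAD must be positive")


@dataclass
class PlanSpec:
    """Beam arrangement, prescriptions and normalization target."""

    gantry_angles_deg: tuple = DEFAULT_GANTRY_ANGLES
    beam_weights: tuple | None = None  # default: equal weights
    isocenter_mm: tuple | None = None  # default: ptv_nx centroid (see auto_plan)
    field_sizes_mm: tuple | None = None  # per-beam BEV (a_lo, a_hi, b_lo, b_hi); see auto_plan
    field_margin_mm: float = 5.0
    prescriptions_gy: dict = field(default_factory=lambda: dict(DEFAULT_PRESCRIPTIONS_GY))
    fractions: int = 33
    dose_grid_spacing_mm: float = 2.0
    normalization_roi: str = "ptv_nx"

    def __post_init__(self):
        angles = tuple(float(a) for a in self.gantry_angles_deg)
        if any(not (0 <= a < 360) for a in angles):
            raise ConfigError("gantry angles must lie in [0, 360)")
        self.gantry_angles_deg = angles
        if self.beam_weights is None:
            self.beam_weights = tuple(1.0 for _ in angles)
        self.beam_weights = tuple(float(w) for w in self.beam_weights)
        if len(self.beam_weights) != len(angles):
            raise ConfigError("one weight per beam required")
        if any(w < 0 for w in self.beam_weights) or not any(w > 0 for w in self.beam_weights):
            raise ConfigError("beam weights must be >= 0 with at least one > 0")
        if any(v <= 0 for v in self.prescriptions_gy.values()) or self.fractions <= 0:
            raise ConfigError("prescriptions and fractions must be positive")


@dataclass
class DoseGrid:
    """A computed dose distribution plus engine provenance."""

    dose: ImageVolume
    plan: PlanSpec
    provenance: dict


def _beam_frame(angle_deg: float):
    th = math.radians(angle_deg)
    u = np.array([-math.sin(th), math.cos(th), 0.0])  # beam direction
    v = np.array([math.cos(th), math.sin(th), 0.0])  # BEV horizontal
    w = np.array([0.0, 0.0, 1.0])  # BEV vertical (patient z)
    return u, v, w


def snap_to_roi_voxel(structures: StructureSet, roi: str) -> np.ndarray:
    """ROI centroid snapped to the nearest in-ROI voxel center (world mm)."""
    mask = structures[roi].mask
    centroid = structures[roi].centroid_index()
    idx = np.argwhere(mask)
    nearest = idx[np.argmin(((idx - centroid) ** 2).sum(axis=1))]
    return structures.grid.index_to_world(nearest.astype(float))


def auto_plan(plan: PlanSpec, structures: StructureSet) -> PlanSpec:
    """Fill in geometry the plan derives from anatomy: isocenter at the
    (snapped) ptv_nx centroid, and per-beam rectangular apertures
    bounding the projected outermost target plus the field margin."""
    iso = plan.isocenter_mm
    if iso is None:
        if "ptv_nx" not in structures or structures["ptv_nx"].voxel_count == 0:
            raise ConfigError("cannot default isocenter: ptv_nx is missing or empty")
        iso = tuple(snap_to_roi_voxel(structures, "ptv_nx"))
    field_sizes = plan.field_sizes_mm
    if field_sizes is None:
        outer = "ptv_2" if "ptv_2" in structures else "ptv_nx"
        pts = structures.grid.index_to_world(
            np.argwhere(structures[outer].mask).astype(float)
        )
        sizes = []
        for angle in plan.gantry_angles_deg:
            u, v, w = _beam_frame(angle)
            sad = 1435.0  # aperture defined at isocenter plane; SAD scaling
            source = np.asarray(iso) - sad * u
            q = pts - source
            du = q @ u
            a = (q @ v) * sad / du
            b = (q @ w) * sad / du
            m = plan.field_margin_mm
            sizes.append(
                (
                    float(a.min() - m),
                    float(a.max() + m),
                    float(b.min() - m),
                    float(b.max() + m),
                )
            )
        field_sizes = tuple(sizes)
    out = PlanSpec(
        gantry_angles_deg=plan.gantry_angles_deg,
        beam_weights=plan.beam_weights,
        isocenter_mm=tuple(float(x) for x in iso),
        field_sizes_mm=field_sizes,
        field_margin_mm=plan.field_margin_mm,
        prescriptions_gy=dict(plan.prescriptions_gy),
        fractions=plan.fractions,
        dose_grid_spacing_mm=plan.dose_grid_spacing_mm,
        normalization_roi=plan.normalization_roi,
    )
    return out


def radiological_depth(red: ImageVolume, source, target) -> float:
    """Exact line integral of rED (in cm) between two world points.

    Siddon-style traversal: the segment is cut at every voxel-boundary
    crossing and each piece contributes its Euclidean length times the
    rED of the voxel it lies in.  Symmetric in the endpoint order;
    regions outside the grid contribute nothing.
    """
    p0 = np.asarray(source, dtype=float)
    p1 = np.asarray(target, dtype=float)
    seg = p1 - p0
    length = float(np.linalg.norm(seg))
    if length == 0.0:
        return 0.0
    grid = red.grid
    origin = np.asarray(grid.origin)
    spacing = np.asarray(grid.spacing)
    shape = np.asarray(grid.shape)

    # Parametric crossings with voxel boundary planes on each axis.
    ts = [np.array([0.0, 1.0])]
    for a in range(3):
        if seg[a] == 0.0:
            continue
        # boundary planes at origin - spacing/2 + k*spacing, k = 0..n
        planes = origin[a] - spacing[a] / 2 + spacing[a] * np.arange(shape[a] + 1)
        t = (planes - p0[a]) / seg[a]
        ts.append(t[(t > 0.0) & (t < 1.0)])
    t_all = np.unique(np.concatenate(ts))
    t_all = t_all[(t_all >= 0.0) & (t_all <= 1.0)]
    mids = (t_all[:-1] + t_all[1:]) / 2
    lens = (t_all[1:] - t_all[:-1]) * length
    pts = p0 + mids[:, None] * seg
    idx = np.round(grid.world_to_index(pts)).astype(int)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    if not np.any(inside):
        return 0.0
    ii = idx[inside]
    vals = red.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float((vals * lens[inside]).sum() / 10.0)  # mm -> cm


def find_interfaces(red: np.ndarray, drop_threshold: float) -> list[tuple[int, int, float]]:
    """Locate sharp density drops along a ray of rED samples.

    The drop is measured across a two-sample window, ``red[i] -
    red[i+2]``, so that a step boundary split across two samples by
    linear interpolation is still recognized.  Consecutive qualifying
    windows are merged into one interface at the steepest window.
    Returns ``(upstream_index, downstream_index, drop)`` triples.
    """
    if red.size < 3:
        return []
    d2 = red[:-2] - red[2:]
    hits = np.nonzero(d2 >= drop_threshold)[0]
    if hits.size == 0:
        return []
    def emit(run):
        best = max(run, key=lambda i: d2[i])
        # Assign the window's middle sample to whichever side of the
        # boundary it is closer to.
        mid_dense = red[best + 1] >= (red[best] + red[best + 2]) / 2.0
        i_up = best + 1 if mid_dense else best
        i_down = best + 2 if mid_dense else best + 1
        return (i_up, i_down, float(d2[best]))

    interfaces = []
    run = [hits[0]]
    for idx in hits[1:]:
        if idx == run[-1] + 1:
            run.append(idx)
        else:
            interfaces.append(emit(run))
            run = [idx]
    interfaces.append(emit(run))
    return interfaces


def ere_perturbation(
    dose: np.ndarray, red: np.ndarray, kernel: EREKernel, step_mm: float
) -> np.ndarray:
    """Apply the magnetic-boundary kernel to one ray.

    At every interface where the density drops by at least the kernel
    threshold (see :func:`find_interfaces`), a fraction of the
    downstream dose - exponentially weighted from the interface, scaled
    with the drop magnitude - is removed and re-deposited on the
    upstream, dense side with the same exponential range.  The ray
    integral is conserved to machine precision; with no qualifying
    interface the ray is returned unchanged.
    """
    interfaces = find_interfaces(np.asarray(red, dtype=float), kernel.drop_threshold)
    if not interfaces or kernel.enhancement == 0.0:
        return dose
    out = dose.astype(float).copy()
    n = out.size
    t = np.arange(n) * step_mm
    for i_up, i_down, drop in interfaces:
        frac = kernel.enhancement * min(drop, 1.0)
        down = slice(i_down, n)
        w_down = np.exp(-(t[down] - t[i_down]) / kernel.range_mm)
        removed = frac * out[down] * w_down
        total = removed.sum()
        if total <= 0.0:
            continue
        out[down] -= removed
        up = slice(0, i_up + 1)
        w_up = np.exp(-(t[i_up] - t[up]) / kernel.range_mm)
        out[up] += total * w_up / w_up.sum()
    return out


def _support_bbox(red: ImageVolume, margin_mm: float = 10.0):
    """Index bounds of the dense support (body) plus a margin."""
    support = red.values > 0.05
    if not support.any():
        return tuple((0, s) for s in red.shape)
    bounds = []
    for a in range(3):
        axes = tuple(i for i in range(3) if i != a)
        prof = support.any(axis=axes)
        lo, hi = np.nonzero(prof)[0][[0, -1]]
        pad = int(math.ceil(margin_mm / red.spacing[a]))
        bounds.append((max(0, lo - pad), min(red.shape[a], hi + pad + 1)))
    return tuple(bounds)


def compute_dose(
    red: ImageVolume,
    plan: PlanSpec,
    model: BeamModel | None = None,
    norm_factor: float | None = None,
) -> DoseGrid:
    """Compute the plan's dose on an rED map.

    If ``norm_factor`` is None the dose is scaled so the isocenter
    receives the normalization ROI's prescription (reference-plan
    normalization); pass the reference run's factor to recalculate the
    frozen plan on a synthetic CT.
    """
    if red.unit != "rED":
        raise UsageError("compute_dose expects an rED volume")
    model = model or BeamModel()
    if plan.isocenter_mm is None or plan.field_sizes_mm is None:
        raise ConfigError("plan lacks isocenter/field sizes; run auto_plan first")
    iso = np.asarray(plan.isocenter_mm, dtype=float)
    grid = red.grid

    (x0, x1), (y0, y1), (z0, z1) = _support_bbox(red)
    xs, ys, zs = grid.world_coordinates()
    gx, gy, gz = np.meshgrid(xs[x0:x1], ys[y0:y1], zs[z0:z1], indexing="ij")
    vox = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    # Ray-grid extents: the body must be inside the traversed t-range.
    corner_pts = np.array(
        [
            (cx, cy, cz)
            for cx in (xs[x0], xs[x1 - 1])
            for cy in (ys[y0], ys[y1 - 1])
            for cz in (zs[z0], zs[z1 - 1])
        ]
    )
    r_body = float(np.linalg.norm(corner_pts - iso, axis=1).max()) + 6.0

    step = float(min(grid.spacing))
    dose = np.zeros(grid.shape)
    sad = model.sad_mm
    sigma = model.penumbra_sigma_mm
    mu = model.mu_eff_cm
    d_build = model.buildup_cm

    for angle, weight, fs in zip(plan.gantry_angles_deg, plan.beam_weights, plan.field_sizes_mm):
        if weight == 0.0:
            continue
        u, v, w = _beam_frame(angle)
        source = iso - sad * u
        a_lo, a_hi, b_lo, b_hi = fs
        pad = 3.0 * sigma + 6.0
        a_samp = np.arange(a_lo - pad, a_hi + pad + step, step)
        b_samp = np.arange(b_lo - pad, b_hi + pad + step, step)
        t_samp = np.arange(sad - r_body, sad + r_body + step, step)
        na, nb, nt = a_samp.size, b_samp.size, t_samp.size

        # Sample rED along diverging rays indexed by BEV offsets (a, b).
        dir_a = a_samp / sad
        dir_b = b_samp / sad
        dirs = (
            u[None, None, :]
            + dir_a[:, None, None] * v[None, None, :]
            + dir_b[None, :, None] * w[None, None, :]
        )
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        pts = source[None, None, None, :] + t_samp[None, None, :, None] * dirs[:, :, None, :]
        idx = grid.world_to_index(pts.reshape(-1, 3))
        red_ray = ndimage.map_coordinates(
            red.values, idx.T, order=1, mode="constant", cval=0.001
        ).reshape(na, nb, nt)

        # Radiological depth (cm) and primary dose along each ray.
        raddepth = np.cumsum(red_ray, axis=2) * (step / 10.0)
        buildup = np.clip(raddepth / d_build, 0.0, 1.0)
        attn = np.exp(-mu * np.maximum(raddepth - d_build, 0.0))
        inv_sq = (sad / t_samp) ** 2
        prof_a = 0.5 * (
            erf((a_samp - a_lo) / (math.sqrt(2) * sigma))
            - erf((a_samp - a_hi) / (math.sqrt(2) * sigma))
        )
        prof_b = 0.5 * (
            erf((b_samp - b_lo) / (math.sqrt(2) * sigma))
            - erf((b_samp - b_hi) / (math.sqrt(2) * sigma))
        )
        beam_dose = (
            weight
            * buildup
            * attn
            * inv_sq[None, None, :]
            * prof_a[:, None, None]
            * prof_b[None, :, None]
        )

        # Magnetic boundary effect, ray by ray (only rays with a
        # qualifying density drop are touched).
        if model.b_on and model.ere.enhancement > 0:
            drops = red_ray[:, :, :-2] - red_ray[:, :, 2:]
            hit = np.any(drops >= model.ere.drop_threshold, axis=2)
            for ia, ib in np.argwhere(hit):
                beam_dose[ia, ib] = ere_perturbation(
                    beam_dose[ia, ib], red_ray[ia, ib], model.ere, step
                )

        # Pull the beam dose back onto the Cartesian grid.
        q = vox - source
        du = q @ u
        t_vox = np.linalg.norm(q, axis=1)
        a_vox = (q @ v) * sad / du
        b_vox = (q @ w) * sad / du
        ia = (a_vox - a_samp[0]) / step
        ib = (b_vox - b_samp[0]) / step
        it = (t_vox - t_samp[0]) / step
        contrib = ndimage.map_coordinates(
            beam_dose, np.stack([ia, ib, it]), order=1, mode="constant", cval=0.0
        )
        dose[x0:x1, y0:y1, z0:z1] += contrib.reshape(x1 - x0, y1 - y0, z1 - z0)

    dose = np.maximum(dose, 0.0)
    rx = plan.prescriptions_gy.get(plan.normalization_roi)
    applied = norm_factor
    if applied is None:
        if rx is None:
            raise ConfigError(
                f"no prescription for normalization ROI {plan.normalization_roi!r}"
            )
        iso_idx = grid.world_to_index(iso)
        d_iso = float(
            ndimage.map_coordinates(dose, iso_idx.reshape(3, 1), order=1)[0]
        )
        if d_iso <= 0:
            raise ConfigError("zero dose at the isocenter; cannot normalize")
        applied = rx / d_iso
    dose *= applied

    vol = ImageVolume(dose, grid, "Gy")
    provenance = {
        "engine": "divergent-ray primary + magnetic boundary kernel",
        "model": {
            "mu_eff_cm": mu,
            "buildup_cm": d_build,
            "penumbra_sigma_mm": sigma,
            "sad_mm": sad,
            "b_on": model.b_on,
            "ere": {
                "drop_threshold": model.ere.drop_threshold,
                "enhancement": model.ere.enhancement,
                "range_mm": model.ere.range_mm,
            },
        },
        "norm_factor": float(applied),
    }
    return DoseGrid(vol, plan, provenance)
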