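"""3D global gamma-index analysis between two dose grids.

The gamma index at a reference voxel r is

    gamma(r) = min over e  sqrt( |r-e|^2 / dta^2
                               + (D_eval(e) - D_ref(r))^2 / dD^2 )

minimized over evaluated positions e on a regular sub-voxel search
lattice (step = DTA / interp_fraction, default DTA/10) within a bounded
search radius (default 3 x DTA), with the evaluated dose trilinearly
interpolated at each position.  dD is the dose criterion as a percentage
of the global normalization dose (reference maximum by default, or the
prescription).  Only voxels whose reference dose reaches the low-dose
threshold are evaluated; the pass rate is the percentage of evaluated
voxels with gamma <= 1.

The search enumerates lattice offsets in order of increasing distance
and stops as soon as the distance term alone exceeds the best gamma so
far, which makes the exhaustive semantics affordable on clinical grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dose import DoseGrid
from .errors import ConfigError, UsageError
from .geometry import ImageVolume


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma tolerance criteria (e.g. 1%/1 mm or 3%/3 mm, 10% threshold)."""

    dose_percent: float
    dta_mm: float
    low_dose_threshold_percent: float = 10.0
    normalization: str = "global-max"  # or "prescription"
    prescription_gy: float | None = None
    search_radius_factor: float = 3.0
    interp_fraction: int = 10  # search step = dta / interp_fraction

    def __post_init__(self):
        if self.dose_percent <= 0 or self.dta_mm <= 0:
            raise ConfigError("dose and distance criteria must be positive")
        if not 0 <= self.low_dose_threshold_percent < 100:
            raise ConfigError("low-dose threshold must be in [0, 100)")
        if self.normalization not in ("global-max", "prescription"):
            raise ConfigError("normalization must be 'global-max' or 'prescription'")
        if self.normalization == "prescription" and not self.prescription_gy:
            raise ConfigError("prescription normalization requires prescription_gy")

    @property
    def label(self) -> str:
        return f"{self.dose_percent:g}%/{self.dta_mm:g}mm"


@dataclass
class GammaResult:
    """Gamma map (NaN outside the evaluated set) and its pass rate."""

    gamma_map: ImageVolume
    pass_rate: float
    evaluated_count: int
    criteria: GammaCriteria


def search_offsets(criteria: GammaCriteria, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Search lattice in fractional-voxel units and squared DTA-normalized
    distances, sorted by distance (the zero offset first)."""
    step = criteria.dta_mm / criteria.interp_fraction
    radius = criteria.search_radius_factor * criteria.dta_mm
    n = int(np.floor(radius / step))
    rng = np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3) * step  # mm
    d2 = (offs**2).sum(axis=1)
    keep = d2 <= radius**2 + 1e-12
    offs, d2 = offs[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    offs, d2 = offs[order], d2[order]
    offs_vox = offs / np.asarray(spacing, dtype=float)
    return offs_vox, d2 / criteria.dta_mm**2


@njit(cache=True)
def _gamma_kernel(eval_dose, ref_vals, voxels, offs_vox, dist2n, inv_dd2, cap2):
    nx, ny, nz = eval_dose.shape
    n_vox = voxels.shape[0]
    n_off = offs_vox.shape[0]
    out = np.empty(n_vox)
    for n in range(n_vox):
        i0 = voxels[n, 0]
        j0 = voxels[n, 1]
        k0 = voxels[n, 2]
        dref = ref_vals[n]
        g2 = cap2
        for m in range(n_off):
            if dist2n[m] >= g2:
                break
            x = i0 + offs_vox[m, 0]
            y = j0 + offs_vox[m, 1]
            z = k0 + offs_vox[m, 2]
            if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1 or y > ny - 1 or z > nz - 1:
                continue
            ix = int(np.floor(x))
            iy = int(np.floor(y))
            iz = int(np.floor(z))
            if ix == nx - 1:
                ix -= 1
            if iy == ny - 1:
                iy -= 1
            if iz == nz - 1:
                iz -= 1
            fx = x - ix
            fy = y - iy
            fz = z - iz
            c00 = eval_dose[ix, iy, iz] * (1 - fx) + eval_dose[ix + 1, iy, iz] * fx
            c10 = eval_dose[ix, iy + 1, iz] * (1 - fx) + eval_dose[ix + 1, iy + 1, iz] * fx
            c01 = eval_dose[ix, iy, iz + 1] * (1 - fx) + eval_dose[ix + 1, iy, iz + 1] * fx
            c11 = (
                eval_dose[ix, iy + 1, iz + 1] * (1 - fx)
                + eval_dose[ix + 1, iy + 1, iz + 1] * fx
            )
            c0 = c00 * (1 - fy) + c10 * fy
            c1 = c01 * (1 - fy) + c11 * fy
            val = c0 * (1 - fz) + c1 * fz
            diff = val - dref
            cand = dist2n[m] + diff * diff * inv_dd2
            if cand < g2:
                g2 = cand
        out[n] = np.sqrt(g2)
    return out


def _as_volume(dose) -> ImageVolume:
    if isinstance(dose, DoseGrid):
        return dose.dose
    return dose


def gamma_index(reference, evaluated, criteria: GammaCriteria) -> GammaResult:
    """Compute the 3D gamma map and pass rate of ``evaluated`` against
    ``reference``.  Both doses must already live on the same grid."""
    ref = _as_volume(reference)
    ev = _as_volume(evaluated)
    if not ref.grid.same_geometry(ev.grid):
        raise UsageError("gamma_index requires both doses on the same grid; resample first")

    if criteria.normalization == "global-max":
        d_norm = float(ref.values.max())
    else:
        d_norm = float(criteria.prescription_gy)
    if d_norm <= 0:
        raise UsageError("normalization dose must be positive")
    dd = criteria.dose_percent / 100.0 * d_norm
    threshold = criteria.low_dose_threshold_percent / 100.0 * d_norm

    eval_mask = ref.values >= threshold
    voxels = np.argwhere(eval_mask).astype(np.int64)
    gamma_map = np.full(ref.shape, np.nan)
    if voxels.shape[0] == 0:
        return GammaResult(ImageVolume(gamma_map, ref.grid, "arbitrary-MR"), 100.0, 0, criteria)

    offs_vox, dist2n = search_offsets(criteria, ref.spacing)
    ref_vals = ref.values[eval_mask].astype(np.float64)
    cap2 = criteria.search_radius_factor**2 + (ref_vals.max() / dd) ** 2 + 1.0
    gammas = _gamma_kernel(
        np.ascontiguousarray(ev.values, dtype=np.float64),
        ref_vals,
        voxels,
        np.ascontiguousarray(offs_vox),
        np.ascontiguousarray(dist2n),
        1.0 / dd**2,
        float(cap2),
    )
    gamma_map[eval_mask] = gammas
    pass_rate = 100.0 * float((gammas <= 1.0).mean())
    return GammaResult(
        ImageVolume(gamma_map, ref.grid, "arbitrary-MR"),
        pass_rate,
        int(voxels.shape[0]),
        criteria,
    )
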