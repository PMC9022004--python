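"""Dose engine: ray tracing, primary model, magnetic boundary kernel."""

import numpy as np
import pytest

from sctdosim import (
    BeamModel,
    EREKernel,
    GridSpec,
    ImageVolume,
    PlanSpec,
    auto_plan,
    compute_dose,
    ere_perturbation,
    radiological_depth,
)
from sctdosim.errors import ConfigError


def water_volume(shape=(48, 48, 32), spacing=4.0, red=1.0):
    grid = GridSpec(
        shape,
        tuple(-(n - 1) * spacing / 2 for n in shape),
        (spacing, spacing, spacing),
    )
    return ImageVolume(np.full(shape, red), grid, "rED")


def single_beam_plan(angle=0.0, half=40.0):
    return PlanSpec(
        gantry_angles_deg=(angle,),
        isocenter_mm=(0.0, 0.0, 0.0),
        field_sizes_mm=(((-half, half, -half, half)),),
    )


class TestRadiologicalDepth:
    def test_axis_aligned_water_path(self):
        red = water_volume()
        # ray along +x through 10 voxels of 4 mm water: 4 cm
        p0 = np.array([-20.0, 1.0, 1.0])
        p1 = np.array([20.0, 1.0, 1.0])
        assert radiological_depth(red, p0, p1) == pytest.approx(4.0, abs=1e-12)

    def test_vacuum_path_is_zero(self):
        red = water_volume(red=0.0)
        assert radiological_depth(red, (-20, 0, 0), (20, 0, 0)) == 0.0

    def test_zero_length_segment(self):
        red = water_volume()
        assert radiological_depth(red, (1, 2, 3), (1, 2, 3)) == 0.0

    def test_symmetric_in_endpoint_order(self, rng):
        red = water_volume()
        red.values[:] = rng.random(red.shape)
        p0, p1 = rng.uniform(-60, 60, (2, 3))
        assert radiological_depth(red, p0, p1) == pytest.approx(
            radiological_depth(red, p1, p0), abs=1e-9
        )

    def test_oblique_chord_through_uniform_block(self):
        """Oblique ray fully inside a uniform block integrates to chord
        length times density."""
        red = water_volume(red=0.8)
        p0 = np.array([-40.0, -30.0, -20.0])
        p1 = np.array([40.0, 30.0, 20.0])
        chord_cm = np.linalg.norm(p1 - p0) / 10.0
        assert radiological_depth(red, p0, p1) == pytest.approx(
            0.8 * chord_cm, rel=1e-9
        )

    def test_partial_overlap_counts_only_inside_segment(self):
        red = water_volume()
        # grid spans [-96, 96] mm in x at shape 48, spacing 4
        p0 = np.array([-300.0, 0.0, 0.0])
        p1 = np.array([0.0, 0.0, 0.0])
        # inside-grid portion: from -96 (outer face) to 0 = 96 mm
        assert radiological_depth(red, p0, p1) == pytest.approx(9.6, abs=1e-9)


class TestPlanSpec:
    def test_bad_angles_rejected(self):
        with pytest.raises(ConfigError):
            PlanSpec(gantry_angles_deg=(0.0, 400.0))

    def test_zero_weights_rejected(self):
        with pytest.raises(ConfigError):
            PlanSpec(gantry_angles_deg=(0.0,), beam_weights=(0.0,))

    def test_auto_plan_defaults_isocenter_to_target(self, coarse_structures):
        plan = auto_plan(PlanSpec(), coarse_structures)
        iso = np.asarray(plan.isocenter_mm)
        centroid = coarse_structures.roi_centroid_world("ptv_nx")
        assert np.linalg.norm(iso - centroid) < 10.0
        assert len(plan.field_sizes_mm) == 9

    def test_auto_plan_requires_primary_target(self, coarse_structures):
        from sctdosim.structures import StructureSet

        empty = StructureSet(coarse_structures.grid)
        empty.add("body", "body", coarse_structures.body.mask)
        with pytest.raises(ConfigError):
            auto_plan(PlanSpec(), empty)


class TestPrimaryModel:
    def test_central_axis_decreases_beyond_buildup(self):
        red = water_volume()
        model = BeamModel(b_on=False)
        dose = compute_dose(red, single_beam_plan(0.0), model, norm_factor=1.0)
        # beam 0 travels +y; central axis at x=z=0
        ix = red.shape[0] // 2
        iz = red.shape[2] // 2
        axis = dose.dose.values[ix, :, iz]
        ys = red.grid.world_coordinates()[1]
        inside = axis > 0
        # entrance face is at negative y; skip 2 cm of buildup
        entry = ys[inside][0]
        sel = inside & (ys > entry + 20.0)
        assert np.all(np.diff(axis[sel]) < 0)

    def test_beam_weight_linearity(self):
        red = water_volume()
        model = BeamModel(b_on=False)
        p1 = single_beam_plan()
        p2 = PlanSpec(
            gantry_angles_deg=p1.gantry_angles_deg,
            beam_weights=(2.0,),
            isocenter_mm=p1.isocenter_mm,
            field_sizes_mm=p1.field_sizes_mm,
        )
        d1 = compute_dose(red, p1, model, norm_factor=1.0).dose.values
        d2 = compute_dose(red, p2, model, norm_factor=1.0).dose.values
        assert np.allclose(d2, 2.0 * d1, atol=1e-12)

    def test_upstream_air_slab_raises_downstream_dose(self):
        model = BeamModel(b_on=False)
        water = water_volume()
        slab = water_volume()
        # air slab between y = -40 and y = -20, upstream of the isocenter
        ys = slab.grid.world_coordinates()[1]
        sel = (ys >= -40) & (ys <= -20)
        slab.values[:, sel, :] = 0.001
        d_w = compute_dose(water, single_beam_plan(0.0), model, norm_factor=1.0)
        d_s = compute_dose(slab, single_beam_plan(0.0), model, norm_factor=1.0)
        ix, iz = water.shape[0] // 2, water.shape[2] // 2
        iy = water.shape[1] // 2 + 6  # downstream of the slab
        assert d_s.dose.values[ix, iy, iz] > d_w.dose.values[ix, iy, iz]

    def test_dose_nonnegative_finite_and_deterministic(self, coarse_phantom, coarse_structures):
        from sctdosim import hu_to_red

        red = hu_to_red(coarse_phantom.ct)
        plan = auto_plan(PlanSpec(), coarse_structures)
        a = compute_dose(red, plan, BeamModel())
        b = compute_dose(red, plan, BeamModel())
        assert np.all(np.isfinite(a.dose.values))
        assert np.all(a.dose.values >= 0)
        assert np.array_equal(a.dose.values, b.dose.values)

    def test_normalization_hits_prescription_at_isocenter(self, coarse_phantom, coarse_structures):
        from scipy import ndimage

        from sctdosim import hu_to_red

        red = hu_to_red(coarse_phantom.ct)
        plan = auto_plan(PlanSpec(), coarse_structures)
        grid = compute_dose(red, plan, BeamModel())
        idx = red.grid.world_to_index(np.asarray(plan.isocenter_mm)).reshape(3, 1)
        d_iso = float(ndimage.map_coordinates(grid.dose.values, idx, order=1)[0])
        assert d_iso == pytest.approx(70.0, rel=1e-9)

    def test_norm_factor_reused_not_recomputed(self, coarse_phantom, coarse_structures):
        from sctdosim import hu_to_red

        red = hu_to_red(coarse_phantom.ct)
        plan = auto_plan(PlanSpec(), coarse_structures)
        ref = compute_dose(red, plan, BeamModel())
        factor = ref.provenance["norm_factor"]
        recalc = compute_dose(red, plan, BeamModel(), norm_factor=factor)
        assert recalc.provenance["norm_factor"] == factor
        assert np.array_equal(recalc.dose.values, ref.dose.values)


class TestEREKernel:
    def test_field_off_matches_no_interface_volume(self):
        # A uniform medium whose exit step (0.3 -> air) stays below the
        # drop threshold sees no boundary effect: B on/off agree exactly.
        red = water_volume(red=0.3)
        plan = single_beam_plan()
        on = BeamModel(b_on=True)
        off = BeamModel(b_on=False)
        d_on = compute_dose(red, plan, on, norm_factor=1.0).dose.values
        d_off = compute_dose(red, plan, off, norm_factor=1.0).dose.values
        assert np.array_equal(d_on, d_off)

    def test_homogeneous_ray_identity(self):
        dose = np.linspace(1, 0.5, 50)
        red = np.ones(50)
        out = ere_perturbation(dose, red, EREKernel(), 2.0)
        assert np.array_equal(out, dose)

    def test_step_interface_conserves_ray_integral(self):
        dose = np.exp(-0.02 * np.arange(80))
        red = np.ones(80)
        red[40:] = 0.001  # tissue -> air step
        out = ere_perturbation(dose, red, EREKernel(), 2.0)
        assert out.sum() == pytest.approx(dose.sum(), abs=1e-9)
        # proximal voxel gains, first distal voxels lose
        assert out[39] > dose[39]
        assert out[42] < dose[42]

    def test_interpolated_step_still_detected(self):
        """A boundary smeared over one intermediate sample (as linear
        interpolation produces) still triggers the kernel."""
        dose = np.ones(60)
        red = np.ones(60)
        red[30] = 0.5  # half-way sample
        red[31:] = 0.001
        out = ere_perturbation(dose, red, EREKernel(), 2.0)
        assert not np.array_equal(out, dose)
        assert out.sum() == pytest.approx(dose.sum(), abs=1e-9)

    def test_subthreshold_drop_identity(self):
        dose = np.ones(40)
        red = np.ones(40)
        red[20:] = 0.8  # drop of 0.2 < threshold 0.4
        out = ere_perturbation(dose, red, EREKernel(), 2.0)
        assert np.array_equal(out, dose)

    def test_enhancement_zero_identity(self):
        dose = np.ones(40)
        red = np.ones(40)
        red[20:] = 0.001
        out = ere_perturbation(dose, red, EREKernel(enhancement=0.0), 2.0)
        assert np.array_equal(out, dose)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ConfigError):
            EREKernel(enhancement=1.0)
        with pytest.raises(ConfigError):
            EREKernel(range_mm=0.0)
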