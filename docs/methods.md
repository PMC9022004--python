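# Methods

This note documents the models, conventions and numerical choices behind
`sctdosim`, and what the synthetic phantoms can and cannot tell you about
clinical data.

## Geometry and conventions

All volumes live on axis-aligned regular grids in the patient **LPS** frame
(+x left, +y posterior, +z superior). Voxel indices are 0-based and the
world coordinate of a voxel is its center: `world = origin + index·spacing`.
Rigid transforms are proper rotations plus translations in world mm; a
structure set's transform maps the planning-CT frame into the MRI frame (the
ground-truth registration). Contours propagate with nearest-neighbor
resampling, intensities with trilinear — standard treatment-planning-system
behavior. Resampling beyond a volume's support fills with a unit-appropriate
background (−1000 HU, rED 0.001, 0 Gy) so out-of-body space behaves as air;
the rED background is 0.001 rather than 0 to avoid degenerate path
integrals. The planning-CT grid is the comparison grid for every dose
evaluation: synthetic CTs are built on the MRI frame and resampled back.

## Digital head phantom

The generator emulates the density topology a nasopharyngeal case presents
to a bulk-assignment workflow, not anatomy: an ellipsoidal head (body), a
6 mm cranial bone shell truncated below z = −30 mm, two internal air
cavities (nasopharyngeal and sinus-like), four nested/adjacent planning
target volumes with the primary target (ptv_nx) overlapping the
nasopharyngeal cavity, and brainstem, cord and parotid organs at risk.
Default grid: 128×128×96 at 2 mm isotropic — finer than needed for the
physics but coarse enough that a full ten-subject cohort runs in minutes on
one CPU; spacing is configurable (the clinical reference acquisition uses
3 mm slices and a 2 mm dose grid).

Hounsfield intensities are Gaussian per tissue class plus additive imaging
noise (default 10 HU): soft tissue 35 ± 12 HU, cranium 570 ± 50 HU, cavity
air −745 ± 60 HU. With the default calibration curve these means map to
cranium rED ≈ 1.32 and cavity rED ≈ 0.26, inside the clinically reported
patient ranges (1.280–1.362 and 0.196–0.327); because each class stays
within one linear calibration segment, the ROI mean rED equals the curve at
the mean HU up to sampling noise. Soft-structure (target/OAR) densities are
water-adjacent and are flagged as assumptions in the phantom's truth record
— no per-organ electron densities are tabulated for them here.

The pseudo-MRI is a monotone intensity remap of tissue class moved into the
MRI frame by a known rigid transform (default 3 mm translation + 2°
rotation, enough to exercise contour propagation while remaining
recoverable), plus independent noise. No pipeline stage uses MR intensities
quantitatively — bulk assignment is contour-driven — so no attempt is made
at MR contrast realism. Not modeled at all: organ texture, dental artifacts
(the emulated cohort excluded implants), neck flexion differences between
scans, deformable anatomy change. Consequently, passing tests show the
*pipeline arithmetic* is right under ideal registration; they say nothing
about registration error, which the clinical workflow lists as its main
uncertainty.

## HU → rED calibration and segmentation

The calibration curve is piecewise linear, clamped at both ends, with
default nodes (−1000, 0.001), (−300, 0.71), (0, 1.0), (250, 1.12),
(1200, 1.72) — a generic scanner-like curve containing the water node; the
true scanner curve is site-specific, so the curve is config-replaceable and
every downstream property is curve-agnostic or band-based. Bone and air are
segmented by thresholds (HU > 250, HU < −300) inside the body mask;
deterministic morphology (binary closing radius 1 voxel, minimum component
0.5 cm³) replaces the manual contour editing a physicist would do, and both
parameters are exposed because that manual step is irreproducible. Exterior
air is excluded by the body mask: the "air" ROI means internal cavities.

## Bulk assignment

An assignment table maps each ROI to one rED with a total precedence order;
a voxel takes the value of the highest-precedence ROI containing it. Default
precedence (low→high): body < targets < OARs < bone < air. Air must outrank
the targets it sits inside — assigning target tissue density to cavity air is
precisely the error the tailored strategy corrects — but the layering is
fully configurable. The three strategies: `homogeneity` (body = 1.0),
`icru` (bone 1.61, air 0.001, rest patient-specific means), `tailor` (every
ROI its patient-specific planning-CT mean). With identity registration the
tailored map reproduces each non-overlapped ROI's planning-CT mean exactly
(conservation by construction, tested to 1e-12).

## Dose engine

A Monte Carlo engine is deliberately out of scope. The engine here is the
smallest model that responds to the two mechanisms bulk assignment perturbs:

1. **Primary term.** Per beam (nine co-planar gantry angles, source-axis
   distance 1435 mm), dose along diverging rays is
   `weight · (SAD/t)² · B(d) · exp(−μ_eff·max(d−d_b, 0))`, where `d` is the
   radiological depth (cm of rED-weighted path), `B(d) = min(d/d_b, 1)` a
   linear buildup ramp over `d_b` = 1.5 cm, and `μ_eff` = 0.049 cm⁻¹ an
   effective 7 MV-FFF-like attenuation. The lateral profile is an
   error-function rectangle (penumbra σ = 3 mm) bounding the projected
   outermost target plus a 5 mm margin. Rays are sampled on a
   beam's-eye-view lattice at the grid pitch; the beam dose is interpolated
   back onto the Cartesian grid. Scatter is ignored; `μ_eff` is effective
   rather than spectral. These are acknowledged, documented simplifications.

2. **Magnetic boundary kernel.** With the field on, at every along-ray rED
   drop ≥ 0.4 a fraction of the downstream dose — `enhancement ·
   min(drop, 1)`, exponentially weighted from the interface with range
   15 mm — is removed and re-deposited on the upstream (dense) side with the
   same range. The transfer conserves the ray integral to machine precision
   and is the engine's rendering of the electron return effect: dose
   escalates on the tissue side of a tissue→air interface and collapses
   beyond it. Interface detection measures the drop across a two-sample
   window (merging consecutive hits at the steepest one) because linear
   interpolation of ray samples splits a step boundary across two samples;
   consecutive-sample detection would miss the real CT's tissue→air step
   entirely. The defaults (enhancement 0.3, range 15 mm) put the boundary
   term at the tens-of-percent interface magnitude reported for 1.5 T
   transverse fields; at much weaker settings the boundary term is
   subdominant to the primary attenuation difference and the engine no
   longer exposes the air-assignment error it exists to probe. The kernel is
   a phenomenological transfer, not charged-particle transport: magnitudes
   are indicative only, directions are the meaningful output.

Plans are normalized once, on the reference CT run, so the isocenter (the
snapped primary-target centroid) receives the 70 Gy prescription; the same
factor and beam weights are reused unchanged for every synthetic-CT
recalculation — recalculation without re-optimization, as in an
adapt-to-shape workflow. The engine is deterministic: identical inputs give
bit-identical dose.

## Gamma analysis

Global gamma with dose criterion as a percentage of the reference maximum
(prescription normalization available), 10% low-dose threshold, search
radius 3×DTA, evaluated dose trilinearly interpolated on a sub-voxel search
lattice of step DTA/10. Voxels below the threshold are excluded wherever
they lie (a body-restricted variant is a caller-side mask choice). The
implementation enumerates lattice offsets in increasing distance and stops
when the distance term alone exceeds the running minimum — exhaustive-search
semantics at tractable cost; a brute-force enumeration oracle pins the
equivalence to 1e-9 in the tests. Pure voxel-center gamma was rejected
because it overestimates γ on coarse grids.

## DVH metrics and point dose

Dx% is the dose level at which exactly x% of the ROI volume is covered,
interpolated linearly between the sorted voxel order statistics (clamped to
the hottest voxel above its coverage); D1cc interpolates the level exceeded
by exactly 1 cm³; ROIs under 1 cm³ report D_max with a flag. V100% counts
voxels at or above the ROI's prescription. The ordering D98% ≤ D_mean ≤ D2%
≤ D_max is checked empirically on every run (it is not a theorem for
arbitrary dose distributions, but holds for realistic ones). The "target
center" point is the mask centroid snapped to the nearest in-mask voxel — 
well-defined even for concave masks — and differences are taken against the
reference point dose, matching the percent framing of the emulated cohort's
tables.

## Paired statistics

Cohort cells are mean and standard deviation; the sample (n−1) convention
is the default, with the population convention exposed because the emulated
cohort's published point-dose table prints its spreads that way while its
gamma table uses the sample convention. The significance instrument is the
Wilcoxon signed-rank test in SPSS-style asymptotic form — zero differences
dropped, mid-ranks with tie-corrected variance, two-sided normal p without
continuity correction — which reproduces the published p = 0.005 for ten
uniformly signed pairs (the exact enumeration gives 0.002; the asymptotic
form is therefore what the source used). The exact method (generating-
function enumeration over all sign assignments, n ≤ 20) is the cross-check.

## Cohort orchestration

A study runs seeded subjects independently; one subject's failure marks it
in the report without aborting the cohort. Reports carry content hashes of
every dose grid and the (shared) normalization factor for audit, and the
report JSON is byte-identical across reruns of the same configuration. The
default cohort of ten seeds echoes the ten-patient design of the emulated
study; the acceptance script scales to five subjects, which is sufficient
for the directional summaries it reports.

## Known limitations

* The dose engine is phenomenological: no scatter, no spectra, no real
  electron transport; its percentage differences are indicative, not
  clinical estimates.
* Phantoms are geometric; registration between CT and MRI frames is known
  exactly, so registration error — the dominant clinical uncertainty for
  bulk sCT — is not exercised.
* DICOM support is import-only and best-effort (axial RTDOSE, planar
  RTSTRUCT contours on one frame of reference); NRRD/NIfTI plus a JSON
  manifest are the canonical interchange.
* Segment-level IMRT machinery (apertures, MU constraints) is out of scope;
  fields are target-conformal rectangles.
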