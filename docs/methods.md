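# Methods

## Calibration model

A segmented point target *i* at pixel (x_I, y_I), with pixel-to-mm scale
factors (s_x, s_y), maps to the phantom coordinate frame through

    p_Ph,i = (T_ph_w)_i · (T_w_p)_i · T_p_i · (s_x·x_I, s_y·y_I, 0, 1)ᵀ

where (T_ph_w)_i (world→phantom) and (T_w_p)_i (probe→world) are tracked
rigid poses and T_p_i (image→probe) is the unknown calibration. T_p_i is
parameterized by Euler angles (α, β, γ) in z-y-x sequence —
R = Rz(α)·Ry(β)·Rx(γ) on column vectors — and translations (x, y, z) in mm.
The probe frame is assumed oriented so its x/y/z axes approximate the
beam's elevation/lateral/axial directions; the image plane then sits near
the (α, β, γ) ≈ (90°, 0°, 90°) permutation of the probe axes, and each
parameter has a direct physical reading.

The solver minimizes the mean Euclidean residual
D = (1/n)·Σ‖truth_i − mapped_i‖ over the n targets. Because the targets'
true phantom-frame coordinates are known (digitized), the problem is
well-posed from a single viewing angle provided the targets span the field
of view; no multi-angle sweep is required.

### Optimization

The refinement runs Levenberg–Marquardt on the stacked 3n-vector of
coordinate residuals rather than on the scalar D: the vector objective is
smooth everywhere (D has a cusp at zero residual) and shares D's minimizer
in the noiseless limit. Defaults: parameter tolerance `xtol = 1e-10`,
iteration cap 200 (exposed in `fit()`); non-convergence is reported via the
`converged` flag, not an exception. The start point is always the
closed-form estimate below — never random — so a fit is a pure function of
its inputs.

### Closed-form initialization and oracle

Each target's truth is pulled into the probe frame through the inverted
tracked poses; registering the scaled in-plane image points (z = 0) onto
those probe-frame points with SVD absolute orientation (Kabsch, with
determinant-sign correction so coplanar sets still yield proper rotations)
gives a closed-form calibration. On exact data it *is* the global optimum,
which provides an independent oracle for the iterative solver; under noise
it is a consistent starting point (tests check it stays within 2× of the
refined residual at 0.5 mm segmentation noise).

### Uncertainties

`CalibrationResult.cov_params` is the Gauss–Newton covariance
σ²·(JᵀJ)⁻¹ with σ² the residual mean square on 3n−6 degrees of freedom.
With purely in-plane noise this overstates the uncertainty of the
out-of-plane-constrained parameters (see "Noise model" below); it is a
diagnostic, not a calibrated confidence interval.

## Conventions

- Angles are radians internally; every file format and report serializes
  degrees. Translations are mm throughout.
- Euler extraction uses the canonical branch β ∈ [−π/2, π/2]; at gimbal
  lock (|β| = π/2) the convention γ = 0 resolves the α/γ ambiguity
  deterministically, and the extracted angles always reconstruct the
  rotation exactly.
- Transforms serialize as 16 row-major numbers. Observation tables are CSV
  (see `probecal.io` for the column schema); calibrations are JSON.
- Image coordinates: x lateral rightward, y axial downward, origin at the
  bitmap's top-left. "Left half" for the speed-correction sign convention
  means x less than the arc origin's x.

## Speed-of-sound correction

The machine forms images assuming c_cal = 1540 m/s. For a curvilinear
probe, echoes travel along rays from the footprint's arc center; a target
at in-plane distance D_im from that origin is displaced along its ray by

    δ = (D_im − R) · (1 − c_a / c_cal)

with R the footprint radius and c_a the actual medium speed. With θ the
signed ray angle from axial (positive on the left half),
δx = δ·sinθ, δy = δ·cosθ and the corrected point is (x + δx, y − δy): in
water below body temperature (c_a < c_cal) targets move shallower and
toward the probe axis. The correction is defined on mm coordinates (the
only units in which R is meaningful) and is exactly the identity at
c_a = c_cal; the decomposition satisfies ‖(δx, δy)‖ =
|D_im − R|·|1 − c_a/c_cal| to machine precision.

Water sound speed comes from Marczak's (1997) fifth-order polynomial in
temperature (pure water, atmospheric pressure, 0–95 °C); out-of-range
temperatures are rejected. The arc origin is an explicit input; a helper
places it at (image width/2, −R), i.e. footprint apex at the image's top
center.

Whether correction is applied before or after calibration is left to the
pipeline (the `correct` CLI subcommand rewrites an observation CSV); the
metrics likewise accept corrected or raw views.

## Evaluation metrics

All four metrics pool scalar observations and report mean, sample SD
(n−1 denominator), max, min and the pool size, which must equal the
protocol combinatorics (k calibrations, v views):

| metric | pooled quantity | pool size |
|---|---|---|
| calibration reproducibility | probe-space distance of 5 image points (4 corners + center of the image extent) over calibration pairs | C(k,2)·5 |
| point reconstruction precision | pairwise distances of one pin's world reconstructions | C(v,2)·k |
| point reconstruction accuracy | distance to the digitized truth | v·k |
| distance reconstruction accuracy | signed true − imaged two-pin separation | v_a·v_b·k |

The first three pool non-negative distances; the last is signed, so a
systematically overestimated separation shows as a negative mean. The "4
corners" are those of the rectangular bitmap extent (width = columns·s_x,
height = rows·s_y); the curvilinear fan is not cropped.

## The simulator

The virtual bench emulates an actuator-assisted point-phantom calibration
of a curvilinear probe at a 90 mm depth setting: a probe with a 40 mm
footprint arc radius and a 40° fan half-angle, imaged as a 1200×480 px
bitmap at 0.1875 mm/px (225×90 mm). Two phantoms: a cross-wire (one point
target) and a line of 7 screw heads 15 mm apart. The actuator steps the
probe through 6 depth levels 10 mm apart, the first ~10 mm below the
footprint; the cross-wire target is additionally stationed at 7 lateral
positions per level — 5 at the most superficial level, whose fan is
narrower — for 40 placements, while the collinear phantom shows all screws
inside the fan at each level (the superficial level truncates the outer
pair: again 40 targets over 6 frames).

Coverage modes: `full_fov` spreads stations over ±95% of the local fan
half-width; `central_only` confines them to ±1/6 of it — inside the central
third of the extent — emulating trials where the target column stays near
the image midline. The geometry (40° fan, 40 mm radius, levels at
10–60 mm) was chosen so the superficial level masks exactly two of the
seven screws, and so the central band is narrow enough to starve the
axial-rotation parameter of lateral lever arm, which is the documented
failure mode such coverage produces in practice.

Ground truth: all six calibration parameters are away from the trivial
axis permutation (93°, −2°, 87.5°, 3.7, −21.4, 12.9 mm) so symmetry cannot
mask bugs; the world→phantom pose is likewise non-trivial. Exact probe
poses are constructed per frame so each planned placement is consistent
with the ground-truth chain to machine precision (for collinear frames,
the screw line is mapped exactly and the roll about it fixed
deterministically; all frames of a trial share one orientation, as an
actuator produces).

### Noise model

- Segmentation noise: i.i.d. Gaussian jitter of the pixel coordinates,
  default SD 0.5 mm expressed in pixels (0.5/0.1875 ≈ 2.67 px).
- Tracker noise: each rigid body (probe and phantom) carries 5 non-coplanar
  virtual infrared markers spanning ~100 mm; every frame, each marker's
  world position is perturbed with isotropic Gaussian noise (default SD
  0.15 mm) and the pose refit by absolute orientation. Modeling noise at
  the marker level — not on pose parameters directly — reproduces how an
  optical tracker actually degrades and makes the more-markers-average-
  better effect testable (5-marker poses beat 3-marker poses).

Both defaults are plausible bench magnitudes, configurable, and not claims
about any particular hardware. One structural consequence worth knowing:
segmentation noise lies entirely in the image plane, so parameters
constrained by out-of-plane information (α, γ, elevation translation) are
nearly noise-free under segmentation jitter alone; tracker noise is what
feeds them. Degeneracy studies should therefore run with both noise
sources enabled (the defaults), as a physical system always would.

### What the simulator does not emulate

B-mode image formation (speckle, point-spread function, segmentation bias
near the fan edges), probe-alignment error dynamics, water-temperature
drift, refraction, and synchronization error between image and pose
streams. Passing tests therefore validate the geometry, the solver and the
metrics — not robustness to image-quality effects a physical system would
add.

## Numerical choices and degenerate inputs

- Rigid-transform constructors enforce orthonormality (‖RᵀR−I‖ ≤ 1e-8),
  det = +1 and an exact [0,0,0,1] bottom row.
- `fit_rigid` rejects <3 pairs and collinear sources (second singular
  value below 1e-9 of the first); calibration requires n ≥ 3
  non-degenerate observations and rejects collinear image-point sets.
- Pool SDs use the n−1 denominator; a single-element pool reports SD 0.
- Problem sizes in the test suite match the protocols they check: 40
  targets per calibration, 10 replicate calibrations, 50 views for the
  precision/accuracy pools, 500 replicates for the marker-averaging
  comparison.

## Known limitations

- Gauss–Newton standard errors ignore the anisotropy of the effective
  noise (see above) and correlations induced by shared per-frame poses.
- The central-coverage degeneracy is reproduced qualitatively; its
  magnitude depends on hardware specifics (tracker geometry, marker
  placement) that the simulator only represents generically.
- Only water as the coupling medium: no tissue speed profiles and no
  refraction at interfaces.
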