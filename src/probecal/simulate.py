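"""Virtual freehand-3D-ultrasound test bench.

Emulates the calibration experiments of an actuator-assisted point-phantom
setup with a curvilinear probe: a cross-wire phantom (one point target) or a
7-collinear-screw phantom (15 mm spacing), imaged at 6 actuator depth levels
10 mm apart under a 90 mm depth setting, with target placements covering the
full fan-shaped field of view or confined to its central band. Ground truth
(the image→probe calibration, the tracked poses, the target coordinates) is
known exactly, so the exact pixel position of every target follows from
inverting the calibration chain; measurement error is then layered on as

* segmentation noise — isotropic Gaussian jitter of the pixel coordinates;
* tracker noise — Gaussian perturbation of the infrared-marker (diode)
  positions of the probe's and phantom's rigid bodies, propagated into the
  poses by closed-form rigid refitting (`pose_from_markers`), which is how
  an optical tracker actually degrades: per-marker error partially averages
  out, so more markers give better poses.

Identical seeds give bit-identical observation sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import (
    CalibrationParams,
    CalibrationResult,
    Observation,
    ProbeCalibration,
)
from .geometry import (
    DegenerateConfigurationError,
    EulerZYX,
    RigidTransform,
    euler_zyx_to_transform,
    fit_rigid,
)
from .metrics import View
from .soundspeed import ProbeArcGeometry, arc_origin_from_radius

logger = logging.getLogger(__name__)

__all__ = [
    "PlanningError",
    "SystemTruth",
    "AcquisitionPlan",
    "NoiseModel",
    "FramePlacement",
    "default_system_truth",
    "default_world_to_phantom",
    "default_diode_layout",
    "make_phantom",
    "fan_half_width",
    "plan_acquisition",
    "total_planned_targets",
    "pose_from_markers",
    "simulate_observations",
    "simulate_pin_views",
    "simulate_calibration_replicates",
]

#: interscrew spacing of the collinear phantom, mm
COLLINEAR_SPACING_MM = 15.0
#: depth of the most superficial actuator level below the footprint apex, mm
FIRST_LEVEL_DEPTH_MM = 10.0


class PlanningError(ValueError):
    """Raised when an acquisition plan places targets outside the image."""


@dataclass(frozen=True)
class SystemTruth:
    """Ground-truth description of the simulated system.

    ``true_calib`` is the image→probe transform the solver should recover;
    ``probe_geometry`` the curvilinear arc model; the image is a
    ``image_size_px`` bitmap at ``scale_mm_per_px`` (x, y) with the probe
    fan (half-angle ``fov_half_angle_deg``) opening from the arc apex at the
    top center; ``depth_setting_mm`` is the scanner depth setting.
    """

    true_calib: CalibrationParams
    probe_geometry: ProbeArcGeometry
    image_size_px: tuple[int, int] = (1200, 480)
    scale_mm_per_px: tuple[float, float] = (0.1875, 0.1875)
    depth_setting_mm: float = 90.0
    fov_half_angle_deg: float = 40.0

    def __post_init__(self):
        if self.depth_setting_mm <= 0:
            raise ValueError("depth setting must be positive")
        if min(self.scale_mm_per_px) <= 0:
            raise ValueError("scale factors must be positive")

    @property
    def image_extent_mm(self) -> tuple[float, float]:
        return (self.image_size_px[0] * self.scale_mm_per_px[0],
                self.image_size_px[1] * self.scale_mm_per_px[1])

    @property
    def lateral_center_mm(self) -> float:
        return self.image_extent_mm[0] / 2.0


@dataclass(frozen=True)
class AcquisitionPlan:
    """Actuator acquisition protocol.

    ``phantom_kind`` is ``"cross_wire"`` (single intersection point, probe
    repositioned laterally and in depth) or ``"collinear7"`` (7 screw heads,
    one frame per depth level). ``coverage`` is ``"full_fov"`` or
    ``"central_only"``. Six depth levels 10 mm apart by default.
    """

    phantom_kind: str = "cross_wire"
    coverage: str = "full_fov"
    n_depth_levels: int = 6
    depth_spacing_mm: float = 10.0
    lateral_positions: int = 7
    first_level_depth_mm: float = FIRST_LEVEL_DEPTH_MM

    def __post_init__(self):
        if self.phantom_kind not in ("cross_wire", "collinear7"):
            raise ValueError(f"unknown phantom kind: {self.phantom_kind!r}")
        if self.coverage not in ("full_fov", "central_only"):
            raise ValueError(f"unknown coverage: {self.coverage!r}")
        if self.depth_spacing_mm <= 0 or self.n_depth_levels < 1:
            raise ValueError("depth levels must be >=1 with positive spacing")
        if self.lateral_positions < 1:
            raise ValueError("need at least one lateral position")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the simulator.

    ``seg_sigma_px`` — SD of Gaussian segmentation jitter, pixels;
    ``diode_sigma_mm`` — SD of isotropic marker-position noise, mm;
    ``seed`` — RNG seed (identical seeds reproduce outputs exactly).
    """

    seg_sigma_px: float = 0.5 / 0.1875  # 0.5 mm at the default scale
    diode_sigma_mm: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.seg_sigma_px < 0 or self.diode_sigma_mm < 0:
            raise ValueError("noise SDs must be non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(seg_sigma_px=0.0, diode_sigma_mm=0.0, seed=seed)


@dataclass(frozen=True)
class FramePlacement:
    """One planned image frame: depth level, visible targets and their
    exact in-plane positions (mm, image coordinates)."""

    depth_mm: float
    target_indices: tuple[int, ...]
    image_points_mm: np.ndarray  # (m, 2)


def default_system_truth() -> SystemTruth:
    """Study-condition defaults: 90 mm depth, 0.1875 mm/px, a 40 mm-radius
    arc with a 40° half-angle fan, and a ground-truth calibration with all
    six parameters away from the trivial axis permutation (the image frame
    sits near +90°/0°/+90° of the probe frame because image x/y are the
    probe's lateral/axial directions)."""
    calib = CalibrationParams(
        EulerZYX.from_degrees(93.0, -2.0, 87.5),
        np.array([3.7, -21.4, 12.9]))
    width_mm = 1200 * 0.1875
    geom = ProbeArcGeometry(radius_mm=40.0,
                            origin_mm=arc_origin_from_radius(40.0, width_mm),
                            c_cal=1540.0)
    return SystemTruth(true_calib=calib, probe_geometry=geom)


def default_world_to_phantom() -> RigidTransform:
    """A fixed non-trivial world→phantom pose (tracker-scale offsets)."""
    return euler_zyx_to_transform(EulerZYX.from_degrees(8.0, -5.0, 3.0),
                                  (150.0, -80.0, 600.0))


#: default probe orientation in the world frame during actuator acquisition
_DEFAULT_PROBE_ORIENTATION = euler_zyx_to_transform(
    EulerZYX.from_degrees(95.0, 15.0, -100.0), (0.0, 0.0, 0.0)).rotation


def default_diode_layout() -> np.ndarray:
    """Five non-coplanar marker positions spanning ~100 mm (body frame)."""
    return np.array([
        [0.0, 0.0, 0.0],
        [100.0, 10.0, 0.0],
        [10.0, 90.0, 5.0],
        [80.0, 80.0, 40.0],
        [30.0, 30.0, 70.0],
    ])


def make_phantom(kind: str) -> np.ndarray:
    """Target coordinates in the phantom frame, (n, 3) mm.

    ``cross_wire``: the single wire intersection at the origin.
    ``collinear7``: 7 screw heads along the phantom x-axis, 15 mm apart,
    centered on the origin.
    """
    if kind == "cross_wire":
        return np.zeros((1, 3))
    if kind == "collinear7":
        offs = (np.arange(7) - 3) * COLLINEAR_SPACING_MM
        pts = np.zeros((7, 3))
        pts[:, 0] = offs
        return pts
    raise ValueError(f"unknown phantom kind: {kind!r}")


def fan_half_width(depth_mm: float, truth: SystemTruth) -> float:
    """Lateral half-width of the fan at an image depth below the apex."""
    phi = math.radians(truth.fov_half_angle_deg)
    return (truth.probe_geometry.radius_mm + depth_mm) * math.tan(phi)


def _level_depths(plan: AcquisitionPlan) -> np.ndarray:
    return plan.first_level_depth_mm + plan.depth_spacing_mm * np.arange(
        plan.n_depth_levels)


def _lateral_offsets(n: int, half_span: float) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return np.linspace(-half_span, half_span, n)


def plan_acquisition(plan: AcquisitionPlan,
                     truth: SystemTruth) -> list[FramePlacement]:
    """Lay out the acquisition: which targets appear where, per frame.

    Cross-wire plans image the single target once per frame, at
    ``lateral_positions`` stations per depth level spread over the chosen
    coverage band — except the most superficial level, whose smaller
    lateral extent admits only ``lateral_positions − 2`` stations (5 of 7
    under the defaults, for 40 placements in total). Collinear plans
    produce one frame per depth level containing every screw head inside
    the fan at that depth; under the default geometry the most superficial
    level truncates the outermost pair, again totalling 40 targets.

    Full-FOV coverage spans ±95% of the local fan half-width; central-only
    confines stations to ±1/6 of it (well inside the central third of the
    extent), emulating trials where the targets stay near the image
    midline.
    """
    cx = truth.lateral_center_mm
    width_mm, _ = truth.image_extent_mm
    frames: list[FramePlacement] = []
    for li, depth in enumerate(_level_depths(plan)):
        if depth > truth.depth_setting_mm:
            raise PlanningError(
                f"depth level {depth:.1f} mm exceeds the "
                f"{truth.depth_setting_mm:.1f} mm depth setting")
        hw = fan_half_width(depth, truth)
        if plan.phantom_kind == "cross_wire":
            n = plan.lateral_positions
            if li == 0:
                n = max(n - 2, 1)  # smaller lateral dimension at the top
            span = 0.95 * hw if plan.coverage == "full_fov" else hw / 6.0
            for off in _lateral_offsets(n, span):
                x = cx + off
                if not (0.0 <= x <= width_mm):
                    raise PlanningError(
                        f"planned station x={x:.1f} mm outside the image")
                frames.append(FramePlacement(
                    depth_mm=float(depth), target_indices=(0,),
                    image_points_mm=np.array([[x, depth]])))
        else:  # collinear7: one frame per level, FOV-masked screws
            offs = (np.arange(7) - 3) * COLLINEAR_SPACING_MM
            if plan.coverage == "central_only":
                visible = np.abs(offs) <= hw / 3.0
            else:
                visible = np.abs(offs) <= hw
            idx = np.nonzero(visible)[0]
            if idx.size == 0:
                raise PlanningError(
                    f"no collinear targets visible at depth {depth:.1f} mm")
            pts = np.column_stack([cx + offs[idx],
                                   np.full(idx.size, float(depth))])
            if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > width_mm):
                raise PlanningError("collinear targets fall outside the image")
            frames.append(FramePlacement(
                depth_mm=float(depth),
                target_indices=tuple(int(i) for i in idx),
                image_points_mm=pts))
    return frames


def total_planned_targets(frames: Sequence[FramePlacement]) -> int:
    """Total visible target placements over all frames of a plan."""
    return int(sum(len(f.target_indices) for f in frames))


def pose_from_markers(true_pose: RigidTransform,
                      diode_layout: np.ndarray,
                      sigma_mm: float,
                      rng: np.random.Generator | int | None = None
                      ) -> RigidTransform:
    """Tracked pose estimated from noisy marker positions.

    Each marker's true world position (the pose applied to its body-frame
    location) is perturbed with isotropic Gaussian noise of SD ``sigma_mm``
    and the pose refit by closed-form rigid registration. With zero noise
    the true pose is recovered exactly; with more (non-coplanar) markers
    the per-marker errors average out and the pose error shrinks.
    """
    layout = np.asarray(diode_layout, dtype=float)
    if layout.ndim != 2 or layout.shape[1] != 3 or layout.shape[0] < 3:
        raise DegenerateConfigurationError(
            "diode layout must be at least 3 non-collinear 3-points")
    if sigma_mm == 0:
        return true_pose
    rng = np.random.default_rng(rng)
    world = true_pose.apply(layout)
    noisy = world + rng.normal(0.0, sigma_mm, size=world.shape)
    return fit_rigid(layout, noisy)


def _frame_probe_pose(frame: FramePlacement,
                      targets_phantom: np.ndarray,
                      truth: SystemTruth,
                      phantom_to_world: RigidTransform,
                      probe_orientation: np.ndarray) -> RigidTransform:
    """Exact probe→world pose placing the frame's targets at their planned
    image positions under the ground-truth calibration."""
    T_pi = truth.true_calib.as_transform()
    pts3 = np.column_stack([frame.image_points_mm,
                            np.zeros(len(frame.target_indices))])
    q = T_pi.apply(pts3)                                     # probe frame
    w = phantom_to_world.apply(targets_phantom[list(frame.target_indices)])
    if q.shape[0] == 1:
        R = probe_orientation
        t = w[0] - R @ q[0]
        return RigidTransform.from_rotation_translation(R, t)
    # collinear frame: map the target line exactly, roll fixed deterministically
    u_q = q[-1] - q[0]
    u_q /= np.linalg.norm(u_q)
    u_w = w[-1] - w[0]
    u_w /= np.linalg.norm(u_w)

    def _frame_of(u):
        e = np.array([0.0, 0.0, 1.0])
        if abs(u @ e) > 0.9:
            e = np.array([1.0, 0.0, 0.0])
        a = np.cross(u, e)
        a /= np.linalg.norm(a)
        return np.column_stack([u, a, np.cross(u, a)])
    R = _frame_of(u_w) @ _frame_of(u_q).T
    t = w.mean(axis=0) - R @ q.mean(axis=0)
    return RigidTransform.from_rotation_translation(R, t)


def simulate_observations(truth: SystemTruth,
                          plan: AcquisitionPlan,
                          noise: NoiseModel,
                          world_to_phantom: RigidTransform | None = None,
                          probe_orientation: np.ndarray | None = None,
                          rng: np.random.Generator | None = None
                          ) -> list[Observation]:
    """Run the virtual acquisition and return segmented observations.

    Exact pixel coordinates follow from the planned placements (which are
    consistent with the ground-truth chain by construction); segmentation
    noise jitters the pixels, and tracker noise perturbs both rigid bodies'
    marker sets once per frame before the poses are refit. Targets whose
    noisy segmentation leaves the bitmap are excluded with a warning.
    """
    if world_to_phantom is None:
        world_to_phantom = default_world_to_phantom()
    if probe_orientation is None:
        probe_orientation = _DEFAULT_PROBE_ORIENTATION
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    targets = make_phantom(plan.phantom_kind)
    frames = plan_acquisition(plan, truth)
    phantom_to_world = world_to_phantom.invert()
    layout = default_diode_layout()
    sx, sy = truth.scale_mm_per_px
    w_px, h_px = truth.image_size_px
    observations: list[Observation] = []
    for fi, frame in enumerate(frames):
        pose = _frame_probe_pose(frame, targets, truth,
                                 phantom_to_world, probe_orientation)
        # one tracker reading of each rigid body per frame
        probe_meas = pose_from_markers(pose, layout, noise.diode_sigma_mm, rng)
        phantom_meas = pose_from_markers(phantom_to_world, layout,
                                         noise.diode_sigma_mm, rng)
        world_to_phantom_meas = phantom_meas.invert()
        for k, ti in enumerate(frame.target_indices):
            px = frame.image_points_mm[k] / (sx, sy)
            if noise.seg_sigma_px > 0:
                px = px + rng.normal(0.0, noise.seg_sigma_px, size=2)
            if not (0 <= px[0] <= w_px and 0 <= px[1] <= h_px):
                logger.warning(
                    "frame %d target %d segmented outside the bitmap "
                    "(%.1f, %.1f px); excluded", fi, ti, px[0], px[1])
                continue
            observations.append(Observation(
                target_id=f"f{fi:02d}_t{ti}",
                pixel=px,
                scale=np.array([sx, sy]),
                world_to_phantom=world_to_phantom_meas,
                probe_to_world=probe_meas,
                truth_phantom=targets[ti],
            ))
    return observations


def simulate_pin_views(truth: SystemTruth,
                       n_views: int,
                       noise: NoiseModel,
                       pin_world: np.ndarray | None = None,
                       max_tilt_deg: float = 30.0,
                       rng: np.random.Generator | None = None
                       ) -> tuple[list[View], np.ndarray]:
    """Image a fixed pin head from many viewing angles and positions.

    Each view draws a uniform in-fan pixel location and a probe orientation
    tilted up to ``max_tilt_deg`` about each axis from the reference
    orientation, then solves the exact probe position that puts the pin at
    that pixel; tracker and segmentation noise are applied as in
    `simulate_observations`. Returns the views and the pin's true world
    coordinates.
    """
    if n_views < 1:
        raise ValueError("need at least one view")
    if pin_world is None:
        pin_world = np.array([50.0, -30.0, 450.0])
    pin_world = np.asarray(pin_world, dtype=float)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    T_pi = truth.true_calib.as_transform()
    layout = default_diode_layout()
    sx, sy = truth.scale_mm_per_px
    cx = truth.lateral_center_mm
    views: list[View] = []
    while len(views) < n_views:
        depth = rng.uniform(5.0, truth.depth_setting_mm - 5.0)
        off = rng.uniform(-0.9, 0.9) * fan_half_width(depth, truth)
        tilt = rng.uniform(-math.radians(max_tilt_deg),
                           math.radians(max_tilt_deg), size=3)
        R_view = _DEFAULT_PROBE_ORIENTATION @ euler_zyx_to_transform(
            EulerZYX(*tilt)).rotation
        q = T_pi.apply(np.array([cx + off, depth, 0.0]))
        pose = RigidTransform.from_rotation_translation(
            R_view, pin_world - R_view @ q)
        pose_meas = pose_from_markers(pose, layout, noise.diode_sigma_mm, rng)
        px = np.array([(cx + off) / sx, depth / sy])
        if noise.seg_sigma_px > 0:
            px = px + rng.normal(0.0, noise.seg_sigma_px, size=2)
        views.append(View(pixel=px, scale=np.array([sx, sy]),
                          probe_to_world=pose_meas))
    return views, pin_world


def simulate_calibration_replicates(truth: SystemTruth,
                                    plan: AcquisitionPlan,
                                    noise: NoiseModel,
                                    n_replicates: int,
                                    base_seed: int | None = None
                                    ) -> list[CalibrationResult]:
    """Repeat the acquisition + fit with independent noise realizations.

    Replicate r uses seed ``base_seed + r`` (``base_seed`` defaults to the
    noise model's seed), emulating independent calibration trials of the
    same protocol.
    """
    if base_seed is None:
        base_seed = noise.seed
    results = []
    for r in range(n_replicates):
        obs = simulate_observations(
            truth, plan, replace(noise, seed=base_seed + r))
        results.append(ProbeCalibration(obs).fit())
    return results
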