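"""Speed-of-sound distortion correction for curvilinear probes.

Ultrasound machines place echoes assuming a fixed sound speed
(``c_cal`` = 1540 m/s, soft tissue). When the coupling medium is water at
room temperature the true speed ``c_a`` is lower, so every target appears
too deep along its beam. For a curvilinear probe the beams are rays fanning
out from the arc center of the footprint, so the apparent position of a
point at in-plane distance ``D_im`` from that origin shifts along its ray by

    δ = (D_im − R) · (1 − c_a / c_cal)

where R is the footprint's radius of curvature. Decomposed into the image
axes (x lateral rightward, y axial downward, origin at the top-left of the
bitmap): δx = δ·sinθ, δy = δ·cosθ, with θ the signed angle between the ray
and the axial direction — positive when the target lies in the left half of
the image. The corrected coordinates are (x + δx, y − δy), i.e. targets in
room-temperature water move shallower and toward the probe axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeArcGeometry",
    "RayCorrection",
    "water_sound_speed",
    "arc_origin_from_radius",
    "ray_params",
    "correct_point",
    "ray_correction",
]

# Marczak (1997) fifth-order fit for the speed of sound in pure water at
# atmospheric pressure, valid 0-95 degC (J. Acoust. Soc. Am. 102:2776).
_MARCZAK = (1.402385e3, 5.038813, -5.799136e-2,
            3.287156e-4, -1.398845e-6, 2.787860e-9)


def water_sound_speed(temperature_C: float) -> float:
    """Speed of sound in pure water at atmospheric pressure, m/s.

    Fifth-order polynomial in temperature (Marczak 1997), valid on
    [0, 95] degC; e.g. ≈1482.4 m/s at 20 degC.
    """
    t = float(temperature_C)
    if not math.isfinite(t) or not (0.0 <= t <= 95.0):
        raise ValueError(
            f"temperature {t!r} degC outside the polynomial's 0-95 range")
    return float(sum(c * t ** k for k, c in enumerate(_MARCZAK)))


@dataclass(frozen=True)
class ProbeArcGeometry:
    """Curvilinear footprint model: arc radius, arc-center location, c_cal.

    ``origin_mm`` is the arc center in image coordinates (mm); for a probe
    whose footprint apex touches the top of the bitmap at the lateral
    center, the center sits at (width/2, −R).
    """

    radius_mm: float
    origin_mm: tuple[float, float]
    c_cal: float = 1540.0  # machine's assumed sound speed, m/s

    def __post_init__(self):
        if not self.radius_mm > 0:
            raise ValueError(f"radius must be positive: {self.radius_mm}")
        if not self.c_cal > 0:
            raise ValueError(f"c_cal must be positive: {self.c_cal}")
        object.__setattr__(self, "origin_mm",
                           (float(self.origin_mm[0]), float(self.origin_mm[1])))


def arc_origin_from_radius(radius_mm: float,
                           image_width_mm: float) -> tuple[float, float]:
    """Arc-center location assuming the footprint apex at the image
    x-center, y = 0: (width/2, −R)."""
    return (image_width_mm / 2.0, -float(radius_mm))


@dataclass(frozen=True)
class RayCorrection:
    """One point's ray geometry and speed-correction shift.

    ``d_im_mm`` is the origin-to-point distance, ``theta_rad`` the signed
    ray angle from axial (positive = left half), ``delta`` the (δx, δy)
    shift in mm.
    """

    d_im_mm: float
    theta_rad: float
    delta: tuple[float, float]


def ray_params(point_mm, geometry: ProbeArcGeometry) -> tuple[float, float]:
    """Distance and signed angle of the ray through an in-plane point.

    Returns ``(D_im, θ)``: Euclidean distance from the arc origin, and the
    angle between the origin→point line and the axial (downward) direction,
    positive for points left of the origin's lateral position.

    Raises for points inside the arc (D_im < R): no beam reaches them.
    """
    x, y = float(point_mm[0]), float(point_mm[1])
    ox, oy = geometry.origin_mm
    dx, dy = x - ox, y - oy
    d = math.hypot(dx, dy)
    if d < geometry.radius_mm * (1.0 - 1e-12):
        raise ValueError(
            f"point {(x, y)} lies inside the probe arc "
            f"(D_im={d:.3f} < R={geometry.radius_mm:.3f})")
    theta = math.atan2(-dx, dy)
    return d, theta


def correct_point(point_mm, geometry: ProbeArcGeometry,
                  c_a: float) -> np.ndarray:
    """Apply the ray-model speed-of-sound correction to one in-plane point.

    Shift magnitude δ = (D_im − R)(1 − c_a/c_cal); output is
    (x + δ·sinθ, y − δ·cosθ) in mm. Identity when c_a equals c_cal.
    """
    if not c_a > 0:
        raise ValueError(f"c_a must be positive: {c_a}")
    d, theta = ray_params(point_mm, geometry)
    delta = (d - geometry.radius_mm) * (1.0 - c_a / geometry.c_cal)
    dx = delta * math.sin(theta)
    dy = delta * math.cos(theta)
    return np.array([float(point_mm[0]) + dx, float(point_mm[1]) - dy])


def ray_correction(point_mm, geometry: ProbeArcGeometry,
                   c_a: float) -> RayCorrection:
    """Full ray diagnostics for one point (distance, angle, shift)."""
    d, theta = ray_params(point_mm, geometry)
    delta = (d - geometry.radius_mm) * (1.0 - c_a / geometry.c_cal)
    return RayCorrection(d_im_mm=d, theta_rad=theta,
                         delta=(delta * math.sin(theta),
                                delta * math.cos(theta)))
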