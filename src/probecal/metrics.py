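"""Quality metrics for freehand 3D ultrasound calibrations.

Four standard measures, each summarized as mean/SD/max/min over a pooled
set of observations:

* calibration reproducibility — dispersion in probe space of five fixed
  image points (the four corners and the center of the image extent) across
  repeated calibrations, pooled over all unordered calibration pairs;
* point reconstruction precision — pairwise spread of world-space
  reconstructions of a single physical pin imaged from many views, pooled
  across calibrations;
* point reconstruction accuracy — distance of each reconstruction from the
  digitized true world position, pooled over view × calibration;
* distance reconstruction accuracy — signed difference (true − imaged)
  between a known two-pin separation and the reconstructed separation,
  pooled over every view-pair × calibration.

The first three are non-negative Euclidean distances; the last is signed,
so its minimum can be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .calibration import CalibrationParams
from .geometry import RigidTransform

__all__ = [
    "MetricSummary",
    "View",
    "reconstruct_world",
    "calibration_reproducibility",
    "point_reconstruction_precision",
    "point_reconstruction_accuracy",
    "distance_reconstruction_accuracy",
]


@dataclass(frozen=True)
class MetricSummary:
    """Pooled summary of one evaluation metric (all values mm)."""

    mean: float
    sd: float
    max: float
    min: float
    n_pooled: int

    @classmethod
    def from_pool(cls, values: np.ndarray) -> "MetricSummary":
        v = np.asarray(values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("empty pool")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(mean=float(v.mean()), sd=sd,
                   max=float(v.max()), min=float(v.min()),
                   n_pooled=int(v.size))

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "max": self.max,
                "min": self.min, "n_pooled": self.n_pooled}


@dataclass(frozen=True)
class View:
    """One tracked sighting of a point target (no phantom reference).

    Like an `Observation` but without the phantom pose and ground truth:
    pixel coordinates, scale factors and the tracked probe→world pose.
    """

    pixel: np.ndarray
    scale: np.ndarray
    probe_to_world: RigidTransform

    def __post_init__(self):
        px = np.asarray(self.pixel, dtype=float)
        sc = np.asarray(self.scale, dtype=float)
        if px.shape != (2,) or not np.all(np.isfinite(px)):
            raise ValueError(f"pixel must be a finite (x, y): {px}")
        if sc.shape != (2,) or not np.all(sc > 0):
            raise ValueError(f"scale factors must be positive: {sc}")
        object.__setattr__(self, "pixel", px)
        object.__setattr__(self, "scale", sc)

    @property
    def image_point_mm(self) -> np.ndarray:
        return np.array([self.scale[0] * self.pixel[0],
                         self.scale[1] * self.pixel[1], 0.0])


def reconstruct_world(view: View, calib: CalibrationParams) -> np.ndarray:
    """World coordinates of a viewed target: T_w_p · T_p_i · v_I."""
    return view.probe_to_world.apply(
        calib.as_transform().apply(view.image_point_mm))


def _reconstruct_all(views: Sequence[View],
                     calib: CalibrationParams) -> np.ndarray:
    T = calib.as_transform()
    pts = np.array([T.apply(v.image_point_mm) for v in views])
    return np.array([v.probe_to_world.apply(p)
                     for v, p in zip(views, pts)])


def calibration_reproducibility(calibs: Sequence[CalibrationParams],
                                image_extent: tuple[float, float]
                                ) -> MetricSummary:
    """Spread of five fixed image points across repeated calibrations.

    The four corners and the center of the rectangular image extent
    (width, height in mm) are mapped into probe space with each
    calibration; Euclidean distances over all unordered calibration pairs
    are pooled over the 5 points, giving C(k,2)·5 observations for k
    calibrations.
    """
    calibs = list(calibs)
    if len(calibs) < 2:
        raise ValueError("reproducibility needs at least 2 calibrations")
    w, h = float(image_extent[0]), float(image_extent[1])
    if w <= 0 or h <= 0:
        raise ValueError(f"image extent must be positive: {(w, h)}")
    pts = np.array([[0.0, 0.0, 0.0], [w, 0.0, 0.0], [0.0, h, 0.0],
                    [w, h, 0.0], [w / 2.0, h / 2.0, 0.0]])
    # (k, 5, 3): each evaluation point in probe space under each calibration
    mapped = np.array([c.as_transform().apply(pts) for c in calibs])
    pools = [pdist(mapped[:, j, :]) for j in range(pts.shape[0])]
    return MetricSummary.from_pool(np.concatenate(pools))


def point_reconstruction_precision(views: Sequence[View],
                                   calibs: Sequence[CalibrationParams]
                                   ) -> MetricSummary:
    """Pairwise spread of reconstructions of one pin over many views.

    For each calibration, all views are reconstructed to world points and
    the C(v,2) pairwise distances computed; pools across the k
    calibrations give C(v,2)·k observations.
    """
    views, calibs = list(views), list(calibs)
    if len(views) < 2:
        raise ValueError("precision needs at least 2 views")
    if len(calibs) < 1:
        raise ValueError("precision needs at least 1 calibration")
    pools = [pdist(_reconstruct_all(views, c)) for c in calibs]
    return MetricSummary.from_pool(np.concatenate(pools))


def point_reconstruction_accuracy(views: Sequence[View],
                                  calibs: Sequence[CalibrationParams],
                                  truth_world) -> MetricSummary:
    """Distance of every view × calibration reconstruction from the true
    (digitized) world position of the pin; v·k pooled observations."""
    views, calibs = list(views), list(calibs)
    if len(views) < 1 or len(calibs) < 1:
        raise ValueError("accuracy needs at least 1 view and 1 calibration")
    truth = np.asarray(truth_world, dtype=float)
    pools = [np.linalg.norm(_reconstruct_all(views, c) - truth, axis=1)
             for c in calibs]
    return MetricSummary.from_pool(np.concatenate(pools))


def distance_reconstruction_accuracy(views_a: Sequence[View],
                                     views_b: Sequence[View],
                                     calibs: Sequence[CalibrationParams],
                                     true_distance: float) -> MetricSummary:
    """Signed error of a reconstructed two-pin separation.

    Every (view of pin A, view of pin B, calibration) triple yields an
    imaged distance; the pool holds true − imaged for all v_a·v_b·k
    combinations (signed: overestimated separations give negative values).
    """
    views_a, views_b, calibs = list(views_a), list(views_b), list(calibs)
    if len(views_a) < 1 or len(views_b) < 1 or len(calibs) < 1:
        raise ValueError("needs at least one view of each pin and one calibration")
    if not true_distance > 0:
        raise ValueError(f"true distance must be positive: {true_distance}")
    pools = []
    for c in calibs:
        A = _reconstruct_all(views_a, c)
        B = _reconstruct_all(views_b, c)
        imaged = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
        pools.append(float(true_distance) - imaged.ravel())
    return MetricSummary.from_pool(np.concatenate(pools))
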