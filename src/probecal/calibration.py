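"""Spatial calibration of a freehand 3D ultrasound probe from point targets.

The calibration problem: a point target segmented at pixel ``(x_I, y_I)`` in
the image plane maps to the phantom coordinate system through the chain

    p_Ph = T_ph_w · T_w_p · T_p_i · (s_x·x_I, s_y·y_I, 0, 1)ᵀ

where ``T_ph_w`` (world→phantom) and ``T_w_p`` (probe→world) come from the
optical tracker and ``T_p_i`` (image→probe) is the unknown calibration matrix
governed by six parameters: Euler angles (α, β, γ) in z-y-x sequence and
translations (x, y, z) along the probe's elevation/lateral/axial axes. The
solver minimizes the mean Euclidean residual

    D = (1/n) Σ_i ‖ truth_i − mapped_i ‖

over the n targets by nonlinear least squares on the stacked 3n-vector of
coordinate residuals (a smoother objective with the same minimizer as D in
the noiseless limit), started from a closed-form absolute-orientation
estimate so the whole procedure is deterministic. This single-chain
formulation requires no variation in viewing angle: a well-spread set of
targets across the field of view suffices to constrain all six parameters.

`ProbeCalibration` is the model object (built from observations or a
DataFrame); its :meth:`~ProbeCalibration.fit` returns a `CalibrationResult`
carrying the estimates, their standard errors from the Gauss–Newton
covariance, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import (
    DegenerateConfigurationError,
    EulerZYX,
    RigidTransform,
    euler_zyx_to_transform,
    fit_rigid,
    transform_to_euler_zyx,
)

__all__ = [
    "Observation",
    "CalibrationParams",
    "CalibrationResult",
    "ProbeCalibration",
    "map_image_to_phantom",
    "residual_error",
    "closed_form_init",
    "calibrate",
]


@dataclass(frozen=True)
class Observation:
    """One segmented point target with its tracked poses and ground truth.

    Attributes
    ----------
    target_id : str
        Label for the point target (e.g. ``"L2_P4"`` or a screw index).
    pixel : (2,) array
        Segmented image coordinates (x_I, y_I) in pixels.
    scale : (2,) array
        Pixel-to-mm factors (s_x, s_y), mm/pixel, both > 0.
    world_to_phantom : RigidTransform
        Tracked world→phantom pose at acquisition.
    probe_to_world : RigidTransform
        Tracked probe→world pose at acquisition.
    truth_phantom : (3,) array
        Digitized true target coordinates in the phantom frame, mm.
    """

    target_id: str
    pixel: np.ndarray
    scale: np.ndarray
    world_to_phantom: RigidTransform
    probe_to_world: RigidTransform
    truth_phantom: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixel, dtype=float)
        sc = np.asarray(self.scale, dtype=float)
        tr = np.asarray(self.truth_phantom, dtype=float)
        if px.shape != (2,) or not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError(f"pixel must be finite non-negative (x, y): {px}")
        if sc.shape != (2,) or not np.all(sc > 0):
            raise ValueError(f"scale factors must be positive: {sc}")
        if tr.shape != (3,) or not np.all(np.isfinite(tr)):
            raise ValueError("truth_phantom must be a finite 3-vector")
        object.__setattr__(self, "pixel", px)
        object.__setattr__(self, "scale", sc)
        object.__setattr__(self, "truth_phantom", tr)

    @property
    def image_point_mm(self) -> np.ndarray:
        """Scaled in-plane point (s_x·x_I, s_y·y_I, 0) in mm."""
        return np.array([self.scale[0] * self.pixel[0],
                         self.scale[1] * self.pixel[1], 0.0])


_PARAM_NAMES = ("alpha", "beta", "gamma", "x", "y", "z")


@dataclass(frozen=True)
class CalibrationParams:
    """The six calibration unknowns defining the image→probe transform.

    Angles are Euler z-y-x (axial–lateral–elevation), stored in radians;
    translations (x, y, z) are mm along the probe's elevation, lateral and
    axial axes. Files and reports serialize the angles in degrees.
    """

    angles: EulerZYX
    translation: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float)
        if t.shape != (3,) or not np.all(np.isfinite(t)):
            raise ValueError("translation must be a finite 3-vector (mm)")
        object.__setattr__(self, "translation", t)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "CalibrationParams":
        """From (α, β, γ, x, y, z) with angles in radians."""
        v = np.asarray(v, dtype=float)
        return cls(EulerZYX(v[0], v[1], v[2]), v[3:6])

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.angles.as_array(), self.translation])

    def as_transform(self) -> RigidTransform:
        """The image→probe rigid transform these parameters define."""
        return euler_zyx_to_transform(self.angles, self.translation)

    @classmethod
    def from_transform(cls, T: RigidTransform) -> "CalibrationParams":
        ang, t = transform_to_euler_zyx(T)
        return cls(ang, t)

    def to_dict(self) -> dict:
        """Serializable form: angles in degrees, translations in mm."""
        a, b, g = self.angles.degrees()
        x, y, z = (float(v) for v in self.translation)
        return {"alpha_deg": a, "beta_deg": b, "gamma_deg": g,
                "x_mm": x, "y_mm": y, "z_mm": z}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        ang = EulerZYX.from_degrees(d["alpha_deg"], d["beta_deg"], d["gamma_deg"])
        return cls(ang, np.array([d["x_mm"], d["y_mm"], d["z_mm"]]))


def map_image_to_phantom(obs: Observation,
                         calib: CalibrationParams) -> np.ndarray:
    """Map one segmented target into the phantom frame via the full chain."""
    p_probe = calib.as_transform().apply(obs.image_point_mm)
    return obs.world_to_phantom.apply(obs.probe_to_world.apply(p_probe))


def _residual_vectors(observations: Sequence[Observation],
                      calib: CalibrationParams) -> np.ndarray:
    """(n, 3) array of truth − mapped, mm."""
    T_pi = calib.as_transform()
    out = np.empty((len(observations), 3))
    for i, obs in enumerate(observations):
        p = obs.world_to_phantom.apply(
            obs.probe_to_world.apply(T_pi.apply(obs.image_point_mm)))
        out[i] = obs.truth_phantom - p
    return out


def residual_error(observations: Sequence[Observation],
                   calib: CalibrationParams) -> float:
    """Mean Euclidean residual D over the targets, mm."""
    if len(observations) == 0:
        raise ValueError("residual_error requires at least one observation")
    d = np.linalg.norm(_residual_vectors(observations, calib), axis=1)
    return float(d.mean())


def closed_form_init(observations: Sequence[Observation]) -> CalibrationParams:
    """Closed-form starting estimate of the calibration parameters.

    Moves each target's digitized truth into the probe frame through the
    inverted tracked poses and registers the scaled in-plane image points
    (z = 0) onto them with :func:`~probecal.geometry.fit_rigid`. Exact for
    noiseless data; with noise it lands close enough for local refinement.
    """
    if len(observations) < 3:
        raise DegenerateConfigurationError(
            "closed-form initialization needs at least 3 observations")
    src = np.array([obs.image_point_mm for obs in observations])
    dst = np.array([
        obs.probe_to_world.invert().apply(
            obs.world_to_phantom.invert().apply(obs.truth_phantom))
        for obs in observations
    ])
    return CalibrationParams.from_transform(fit_rigid(src, dst))


class ProbeCalibration:
    """Model object for a probe-calibration fit.

    Parameters
    ----------
    observations : sequence of Observation
        At least 3 non-degenerate segmented point targets.

    Examples
    --------
    >>> model = ProbeCalibration(observations)
    >>> result = model.fit()
    >>> print(result.summary())
    """

    def __init__(self, observations: Sequence[Observation]):
        observations = list(observations)
        if len(observations) < 3:
            raise DegenerateConfigurationError(
                f"calibration requires at least 3 observations, "
                f"got {len(observations)}")
        self.observations = observations
        self.nobs = len(observations)

    @classmethod
    def from_dataframe(cls, df) -> "ProbeCalibration":
        """Build from an observation table (see `probecal.io` for the schema)."""
        from . import io
        return cls(io.observations_from_dataframe(df))

    @classmethod
    def from_csv(cls, path) -> "ProbeCalibration":
        from . import io
        return cls(io.read_observations(path))

    # -- objective --------------------------------------------------------
    def residual_vector(self, params: CalibrationParams) -> np.ndarray:
        """Stacked 3n coordinate residuals (truth − mapped), mm."""
        return _residual_vectors(self.observations, params).ravel()

    def residual_mm(self, params: CalibrationParams) -> float:
        return residual_error(self.observations, params)

    def fit(self, start: CalibrationParams | None = None, *,
            xtol: float = 1e-10, max_iter: int = 200) -> "CalibrationResult":
        """Solve for the six parameters by nonlinear least squares.

        The optimizer refines the stacked 3n-residual objective from the
        closed-form start (never random), so identical inputs always give
        identical output. Non-convergence within the iteration cap is
        reported through ``converged`` on the result, not raised.
        """
        x0 = (start if start is not None else
              closed_form_init(self.observations)).as_vector()

        def fun(v):
            return self.residual_vector(CalibrationParams.from_vector(v))

        sol = least_squares(fun, x0, method="lm", xtol=xtol,
                            ftol=1e-14, gtol=1e-14,
                            max_nfev=max_iter * (len(x0) + 1))
        params = CalibrationParams.from_vector(sol.x)
        m = sol.fun.size
        dof = max(m - 6, 1)
        sigma2 = float(sol.fun @ sol.fun) / dof
        JtJ = sol.jac.T @ sol.jac
        try:
            cov = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = np.full((6, 6), np.nan)
        return CalibrationResult(
            params=params,
            residual_mm=self.residual_mm(params),
            n_targets=self.nobs,
            converged=bool(sol.status > 0),
            iterations=int(sol.nfev),
            cov_params=cov,
            model=self,
        )


@dataclass
class CalibrationResult:
    """Fitted calibration parameters with uncertainties and diagnostics.

    ``cov_params`` is the Gauss–Newton covariance of (α, β, γ, x, y, z)
    (radians/mm) scaled by the residual variance; ``bse`` are its square-root
    diagonal standard errors.
    """

    params: CalibrationParams
    residual_mm: float
    n_targets: int
    converged: bool
    iterations: int
    cov_params: np.ndarray = field(default_factory=lambda: np.full((6, 6), np.nan))
    model: ProbeCalibration | None = None

    def __post_init__(self):
        if self.residual_mm < 0 or self.n_targets < 1:
            raise ValueError("invalid calibration result")

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    @property
    def transform(self) -> RigidTransform:
        return self.params.as_transform()

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(matrix_row_major=self.params.as_transform().as_flat(),
                 residual_mm=float(self.residual_mm),
                 n_targets=int(self.n_targets),
                 converged=bool(self.converged))
        return d

    def summary(self) -> str:
        """Plain-text summary table of the six parameters."""
        est = self.params.as_vector()
        se = self.bse
        deg = 180.0 / math.pi
        rows = []
        for i, name in enumerate(_PARAM_NAMES):
            if i < 3:
                rows.append((f"{name} (deg)", est[i] * deg, se[i] * deg))
            else:
                rows.append((f"{name} (mm)", est[i], se[i]))
        lines = [
            "Probe Calibration Results",
            "=" * 44,
            f"{'n targets':<18}{self.n_targets:>10}",
            f"{'residual D (mm)':<18}{self.residual_mm:>14.6f}",
            f"{'converged':<18}{str(self.converged):>10}",
            f"{'fn evaluations':<18}{self.iterations:>10}",
            "-" * 44,
            f"{'parameter':<14}{'estimate':>14}{'std err':>14}",
            "-" * 44,
        ]
        for name, e, s in rows:
            lines.append(f"{name:<14}{e:>14.5f}{s:>14.5f}")
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot_residuals(self, ax=None):
        """Bar plot of per-target residual distances (mm)."""
        if self.model is None:
            raise ValueError("result has no attached model/observations")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        d = np.linalg.norm(
            _residual_vectors(self.model.observations, self.params), axis=1)
        ax.bar(np.arange(d.size), d, color="#4878a8")
        ax.axhline(self.residual_mm, color="k", ls="--", lw=1,
                   label=f"mean D = {self.residual_mm:.2f} mm")
        ax.set_xlabel("target index")
        ax.set_ylabel("residual (mm)")
        ax.legend(frameon=False)
        return ax


def calibrate(observations: Sequence[Observation],
              **options) -> CalibrationResult:
    """Convenience wrapper: fit a `ProbeCalibration` on the observations."""
    return ProbeCalibration(observations).fit(**options)
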