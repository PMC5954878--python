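"""Rigid-body transform algebra for tracked ultrasound geometry.

All frame changes in the toolkit — image→probe, probe→world, world→phantom —
are 4×4 homogeneous rigid transforms with translations in millimetres.
Rotations are parameterized, where a human-readable form is needed, as Euler
angles in z-y-x sequence (axial, lateral, elevation): ``R = Rz(α)·Ry(β)·Rx(γ)``
acting on column vectors.

The closed-form absolute-orientation solver :func:`fit_rigid` (SVD/Kabsch with
reflection correction) is used to initialize the calibration optimizer, to
refit tracked poses from marker positions, and as a noiseless-case oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateConfigurationError",
    "RigidTransform",
    "EulerZYX",
    "euler_zyx_to_transform",
    "transform_to_euler_zyx",
    "compose",
    "invert",
    "apply",
    "fit_rigid",
]

#: tolerance for the orthonormality / unit-determinant checks
_RIGID_ATOL = 1e-8


class DegenerateConfigurationError(ValueError):
    """Raised when a point configuration cannot determine a rigid transform."""


class RigidTransform:
    """A 4×4 homogeneous rigid-body transform (rotation + translation, mm).

    Invariants are enforced at construction: the rotation block is
    orthonormal with determinant +1 (no reflection) and the bottom row is
    exactly ``[0, 0, 0, 1]``.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {M.shape}")
        if not np.all(np.isfinite(M)):
            raise ValueError("transform contains non-finite entries")
        R = M[:3, :3]
        if np.linalg.norm(R.T @ R - np.eye(3)) > _RIGID_ATOL:
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block is a reflection (det < 0)")
        M = M.copy()
        M[3] = (0.0, 0.0, 0.0, 1.0)
        M.flags.writeable = False
        self.matrix = M

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray,
                                  translation: np.ndarray) -> "RigidTransform":
        M = np.eye(4)
        M[:3, :3] = rotation
        M[:3, 3] = translation
        return cls(M)

    @classmethod
    def from_translation(cls, translation: np.ndarray) -> "RigidTransform":
        return cls.from_rotation_translation(np.eye(3), translation)

    # -- accessors --------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # -- algebra ----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    __matmul__ = compose

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform.from_rotation_translation(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map a 3-point or an (n, 3) array of points through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- misc -------------------------------------------------------------
    def as_flat(self) -> list[float]:
        """Row-major list of the 16 matrix entries (serialization form)."""
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        arr = np.asarray(list(values), dtype=float)
        if arr.size != 16:
            raise ValueError(f"expected 16 values, got {arr.size}")
        return cls(arr.reshape(4, 4))

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        ang, t = transform_to_euler_zyx(self)
        return (f"RigidTransform(zyx_deg=({math.degrees(ang.alpha):.3f}, "
                f"{math.degrees(ang.beta):.3f}, {math.degrees(ang.gamma):.3f}), "
                f"t=({t[0]:.3f}, {t[1]:.3f}, {t[2]:.3f}) mm)")


def _wrap_angle(a: float) -> float:
    """Normalize an angle to (−π, π]."""
    a = math.remainder(a, 2.0 * math.pi)
    if a <= -math.pi:
        a += 2.0 * math.pi
    return a


@dataclass(frozen=True)
class EulerZYX:
    """Euler angles, z-y-x (axial–lateral–elevation) sequence, radians.

    ``alpha`` rotates about z (axial), ``beta`` about y (lateral), ``gamma``
    about x (elevation). Angles are normalized to (−π, π] at construction.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} is not finite: {v!r}")
            object.__setattr__(self, name, _wrap_angle(float(v)))

    @classmethod
    def from_degrees(cls, alpha: float, beta: float, gamma: float) -> "EulerZYX":
        return cls(math.radians(alpha), math.radians(beta), math.radians(gamma))

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def degrees(self) -> tuple[float, float, float]:
        return (math.degrees(self.alpha), math.degrees(self.beta),
                math.degrees(self.gamma))


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def euler_zyx_to_transform(angles: EulerZYX,
                           translation=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build the rigid transform with rotation ``Rz(α)·Ry(β)·Rx(γ)``."""
    t = np.asarray(translation, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise ValueError("translation must be a finite 3-vector")
    R = _rot_z(angles.alpha) @ _rot_y(angles.beta) @ _rot_x(angles.gamma)
    return RigidTransform.from_rotation_translation(R, t)


def transform_to_euler_zyx(T: RigidTransform) -> tuple[EulerZYX, np.ndarray]:
    """Extract z-y-x Euler angles and translation from a rigid transform.

    At gimbal lock (|β| = π/2, where only α∓γ is observable) the convention
    γ = 0 is applied, making the decomposition deterministic; the returned
    angles always reconstruct ``T`` exactly.
    """
    R = T.rotation
    cb = math.hypot(R[2, 1], R[2, 2])
    beta = math.atan2(-R[2, 0], cb)
    if cb < 1e-9:
        # gimbal lock: alpha and gamma share one degree of freedom
        alpha = math.atan2(-R[0, 1], R[1, 1])
        gamma = 0.0
    else:
        alpha = math.atan2(R[1, 0], R[0, 0])
        gamma = math.atan2(R[2, 1], R[2, 2])
    return EulerZYX(alpha, beta, gamma), T.translation.copy()


# -- functional aliases (module surface) ----------------------------------

def compose(A: RigidTransform, B: RigidTransform) -> RigidTransform:
    """``A ∘ B``: the transform applying B first, then A."""
    return A.compose(B)


def invert(T: RigidTransform) -> RigidTransform:
    return T.invert()


def apply(T: RigidTransform, points: np.ndarray) -> np.ndarray:
    return T.apply(points)


def fit_rigid(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid registration (absolute orientation).

    Finds the rigid transform T minimizing Σ‖dst_i − T·src_i‖² by the
    SVD/Kabsch method, with the determinant sign corrected so the result is
    always a proper rotation — valid for coplanar point sets.

    Parameters
    ----------
    src, dst : (n, 3) arrays, n ≥ 3
        Corresponding points; must not be collinear.

    Raises
    ------
    DegenerateConfigurationError
        For fewer than 3 pairs or a collinear source set.
    """
    P = np.asarray(src, dtype=float)
    Q = np.asarray(dst, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape != Q.shape:
        raise ValueError("src and dst must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear iff the centered source has rank < 2
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-9 * max(1.0, sv[0]):
        raise DegenerateConfigurationError("source points are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return RigidTransform.from_rotation_translation(R, cq - R @ cp)
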