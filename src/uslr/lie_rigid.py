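"""Closed-form logarithm and exponential maps on SE(3).

Rigid head motion between scan sessions is parameterised in the Lie algebra
se(3) by a 6-vector ``(q, d)``: ``q`` is the rotation generator
(axis times angle, radians) and ``d`` the translation generator (mm).
In this chart inversion is negation and, to first order in the
Baker-Campbell-Hausdorff series, composition is addition -- the two
properties the graph inference relies on.

All transforms act on world (RAS, mm) coordinates; voxel-to-world handling
lives with the image grid, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RigidMatrix",
    "RigidLog",
    "rigid_log",
    "rigid_exp",
    "rigid_compose",
    "load_rigid_matrix",
    "save_rigid_matrix",
    "load_rigid_log",
    "save_rigid_log",
]

_ORTHO_TOL = 1e-10
# below this angle every sin(phi)/phi-type coefficient switches to its
# 4th-order Taylor expansion
_SMALL_ANGLE = 1e-5
_MAX_ANGLE = np.pi - 1e-6


class SingularRotationError(ValueError):
    """Rotation angle at or above pi - 1e-6: the principal log is not unique."""


@dataclass(frozen=True)
class RigidMatrix:
    """A proper rigid transform: rotation ``U`` (3x3) plus translation ``t`` (mm)."""

    U: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        if U.shape != (3, 3) or not np.all(np.isfinite(U)) or not np.all(np.isfinite(t)):
            raise ValueError("RigidMatrix requires a finite 3x3 rotation and 3-vector translation")
        if not np.allclose(U @ U.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(U), 1.0, atol=1e-8):
            raise ValueError("rotation block has det != +1 (improper rotation)")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "t", t)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.U
        m[:3, 3] = self.t
        return m

    @classmethod
    def identity(cls) -> "RigidMatrix":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidMatrix":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    def inverse(self) -> "RigidMatrix":
        return RigidMatrix(self.U.T, -self.U.T @ self.t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) through the transform."""
        return np.asarray(points, dtype=float) @ self.U.T + self.t


@dataclass(frozen=True)
class RigidLog:
    """se(3) parameters: rotation generator ``q`` (rad*axis), translation generator ``d`` (mm)."""

    q: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float).reshape(3)
        d = np.asarray(self.d, dtype=float).reshape(3)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(d))):
            raise ValueError("RigidLog parameters must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "d", d)

    @property
    def angle(self) -> float:
        return float(np.linalg.norm(self.q))

    @property
    def vector(self) -> np.ndarray:
        """Stacked 6-vector (qx, qy, qz, dx, dy, dz)."""
        return np.concatenate([self.q, self.d])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RigidLog":
        v = np.asarray(v, dtype=float).reshape(6)
        return cls(v[:3], v[3:])

    def __neg__(self) -> "RigidLog":
        return RigidLog(-self.q, -self.d)


def _skew(q: np.ndarray) -> np.ndarray:
    qx, qy, qz = q
    return np.array([[0.0, -qz, qy], [qz, 0.0, -qx], [-qy, qx, 0.0]])


def _rot_coeffs(phi: float) -> tuple[float, float]:
    """Rodrigues coefficients A = sin(phi)/phi, B = (1-cos(phi))/phi^2."""
    if phi < _SMALL_ANGLE:
        p2 = phi * phi
        return 1.0 - p2 / 6.0 + p2 * p2 / 120.0, 0.5 - p2 / 24.0 + p2 * p2 / 720.0
    return np.sin(phi) / phi, (1.0 - np.cos(phi)) / phi**2


def _v_coeff_c(phi: float) -> float:
    """C = (phi - sin(phi))/phi^3, the Q^2 coefficient of the left Jacobian V."""
    if phi < _SMALL_ANGLE:
        p2 = phi * phi
        return 1.0 / 6.0 - p2 / 120.0 + p2 * p2 / 5040.0
    return (phi - np.sin(phi)) / phi**3


def _vinv_coeff(phi: float) -> float:
    """Q^2 coefficient of V^-1: (1 - phi sin(phi) / (2 (1-cos(phi)))) / phi^2."""
    if phi < _SMALL_ANGLE:
        p2 = phi * phi
        return 1.0 / 12.0 + p2 / 720.0 + p2 * p2 / 30240.0
    return (1.0 - phi * np.sin(phi) / (2.0 * (1.0 - np.cos(phi)))) / phi**2


def rigid_log(m: RigidMatrix) -> RigidLog:
    """Principal matrix logarithm of a rigid transform, in closed form.

    The rotation angle is ``phi = arccos((tr(U) - 1)/2)``; ``q`` is the scaled
    skew part of ``U`` and ``d = V^-1 t`` with the SE(3) left-Jacobian inverse
    ``V^-1 = I - Q/2 + c(phi) Q^2``. Canonical branch: ``|q| in [0, pi)``.

    Raises
    ------
    SingularRotationError
        For rotation angles at or above ``pi - 1e-6``, where the axis is not
        determined by the skew part. Longitudinal intra-subject motion is far
        below this; near-pi rotations indicate a data problem.
    """
    U, t = m.U, m.t
    cos_phi = np.clip((np.trace(U) - 1.0) / 2.0, -1.0, 1.0)
    phi = float(np.arccos(cos_phi))
    if phi >= _MAX_ANGLE:
        raise SingularRotationError(f"rotation angle {phi:.6f} rad too close to pi")
    skew_vec = np.array([U[2, 1] - U[1, 2], U[0, 2] - U[2, 0], U[1, 0] - U[0, 1]])
    if phi < _SMALL_ANGLE:
        # q = phi/(2 sin phi) * skew_vec -> (1/2)(1 + phi^2/6 + ...) * skew_vec
        q = 0.5 * (1.0 + phi * phi / 6.0) * skew_vec
    else:
        q = (phi / (2.0 * np.sin(phi))) * skew_vec
    Q = _skew(q)
    v_inv = np.eye(3) - 0.5 * Q + _vinv_coeff(phi) * (Q @ Q)
    return RigidLog(q, v_inv @ t)


def rigid_exp(l: RigidLog) -> RigidMatrix:
    """Closed-form exponential: Rodrigues rotation plus ``t = V d``.

    ``U = I + A Q + B Q^2`` and ``t = (I + B Q + C Q^2) d`` with
    ``A = sin(phi)/phi``, ``B = (1-cos(phi))/phi^2``, ``C = (phi-sin(phi))/phi^3``;
    Taylor limits are used below ``phi = 1e-5`` so ``U -> I + Q`` and ``t -> d``.
    """
    phi = l.angle
    Q = _skew(l.q)
    A, B = _rot_coeffs(phi)
    C = _v_coeff_c(phi)
    Q2 = Q @ Q
    U = np.eye(3) + A * Q + B * Q2
    V = np.eye(3) + B * Q + C * Q2
    return RigidMatrix(U, V @ l.d)


def rigid_compose(
    a: RigidMatrix,
    b: RigidMatrix,
    invert_a: bool = False,
    invert_b: bool = False,
) -> RigidMatrix:
    """Compose two rigid transforms, ``(a or a^-1) . (b or b^-1)`` as point maps."""
    if invert_a:
        a = a.inverse()
    if invert_b:
        b = b.inverse()
    return RigidMatrix(a.U @ b.U, a.U @ b.t + a.t)


# -- text-file interchange ---------------------------------------------------
# 4x4 affine: four whitespace-separated rows, world mm, RAS.
# RigidLog: one line "qx qy qz dx dy dz".


def save_rigid_matrix(m: RigidMatrix, path: str | Path) -> None:
    np.savetxt(path, m.matrix, fmt="%.17g")


def load_rigid_matrix(path: str | Path) -> RigidMatrix:
    arr = np.loadtxt(path)
    if arr.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 affine, got shape {arr.shape}")
    return RigidMatrix.from_matrix(arr)


def save_rigid_log(l: RigidLog, path: str | Path) -> None:
    np.savetxt(path, l.vector[None, :], fmt="%.17g")


def load_rigid_log(path: str | Path) -> RigidLog:
    arr = np.loadtxt(path).reshape(-1)
    if arr.size != 6:
        raise ValueError(f"{path}: expected 6 numbers (qx qy qz dx dy dz), got {arr.size}")
    return RigidLog.from_vector(arr)
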