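"""Rigid transforms on SE(3) and geodesic interpolation.

Slice-to-volume motion correction assigns each high-b slice a pose
interpolated between the two temporally closest low-b poses,

    R(tau) = exp(tau * log(R1) + (1 - tau) * log(R0)),

where log/exp are the principal matrix logarithm and exponential on the
4x4 homogeneous representation of SE(3).  This interpolates a smooth screw
trajectory and stays exactly rigid.  Closed-form Rodrigues-type formulas are
used (no generic matrix log), valid for rotation angles below pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "se3_log", "se3_exp", "interp_rigid"]

_EPS = 1e-12


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid map in scanner millimetre coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has negative determinant")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def from_params(cls, params, centre=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """(tx, ty, tz, rx, ry, rz): translation in mm, intrinsic xyz Euler
        rotation in degrees about ``centre``."""
        params = np.asarray(params, dtype=float)
        R = Rotation.from_euler("xyz", params[3:6], degrees=True).as_matrix()
        c = np.asarray(centre, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = params[:3] + c - R @ c
        return cls(m)

    # -- accessors ----------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def to_params(self, centre=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Inverse of :meth:`from_params` for the same rotation centre."""
        c = np.asarray(centre, dtype=float)
        R = self.rotation
        euler = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = self.translation - c + R @ c
        return np.concatenate([t, euler])

    # -- algebra ------------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = -R @ self.translation
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to points of shape (3, n) or (n, 3) (returned same shape)."""
        pts = np.asarray(points, dtype=float)
        if pts.ndim == 2 and pts.shape[0] == 3:
            return self.rotation @ pts + self.translation[:, None]
        return pts @ self.rotation.T + self.translation

    def rotation_angle(self) -> float:
        """Rotation angle in radians."""
        tr = np.trace(self.rotation)
        return float(np.arccos(np.clip((tr - 1) / 2, -1.0, 1.0)))


def _hat(w: np.ndarray) -> np.ndarray:
    return np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0.0]])


def se3_log(transform: RigidTransform) -> np.ndarray:
    """Principal logarithm of a rigid transform as a 4x4 twist matrix.

    Raises for rotation angles at or beyond pi, where the principal branch
    is not defined/unique.
    """
    R = transform.rotation
    t = transform.translation
    theta = transform.rotation_angle()
    if theta >= np.pi - 1e-9:
        raise ValueError(
            f"rotation angle {np.degrees(theta):.2f} deg >= 180 deg: "
            "principal matrix logarithm undefined"
        )
    if theta < _EPS:
        W = 0.5 * (R - R.T)  # ~ hat(w) to O(theta^3)
        Vinv = np.eye(3) - 0.5 * W
    else:
        W = theta / (2 * np.sin(theta)) * (R - R.T)
        # V^-1 for the translation part of the twist
        A = np.sin(theta) / theta
        B = (1 - np.cos(theta)) / theta**2
        Vinv = (
            np.eye(3) - 0.5 * W
            + (1 / theta**2) * (1 - A / (2 * B)) * (W @ W)
        )
    out = np.zeros((4, 4))
    out[:3, :3] = W
    out[:3, 3] = Vinv @ t
    return out


def se3_exp(twist: np.ndarray) -> RigidTransform:
    """Exponential of a 4x4 twist matrix back onto SE(3)."""
    W = twist[:3, :3]
    u = twist[:3, 3]
    w = np.array([W[2, 1], W[0, 2], W[1, 0]])
    theta = np.linalg.norm(w)
    if theta < _EPS:
        R = np.eye(3) + W + 0.5 * W @ W
        V = np.eye(3) + 0.5 * W
    else:
        A = np.sin(theta) / theta
        B = (1 - np.cos(theta)) / theta**2
        C = (theta - np.sin(theta)) / theta**3
        R = np.eye(3) + A * W + B * (W @ W)
        V = np.eye(3) + B * W + C * (W @ W)
    # re-orthonormalize against floating-point drift
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = V @ u
    return RigidTransform(m)


def interp_rigid(r0: RigidTransform, r1: RigidTransform, tau: float) -> RigidTransform:
    """Geodesic interpolation exp(tau*log(R1) + (1-tau)*log(R0)) on SE(3)."""
    if tau == 0.0:
        return r0
    if tau == 1.0:
        return r1
    return se3_exp(tau * se3_log(r1) + (1.0 - tau) * se3_log(r0))
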