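"""Rigid registration between image and simulation frames.

The simulated ablation is computed in the electrode's own frame and must be
placed in subject (image) coordinates using the electrode pose seen in CT.
Pose recovery is a least-squares rigid fit (Kabsch/Umeyama without scale)
between corresponding point sets built from the tip and resampled tine
polylines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class PoseError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> rotation @ x + translation (mm)."""

    rotation: np.ndarray     # (3,3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad, translation=(0, 0, 0)):
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M


def kabsch(source: np.ndarray, target: np.ndarray) -> tuple:
    """Least-squares rigid transform mapping source onto target.

    Returns (RigidTransform, rms_residual).  Degenerate (collinear or
    coincident) point sets raise :class:`PoseError` since the rotation is
    then not unique.
    """
    P = np.asarray(source, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise PoseError("need matching point sets with at least 3 points")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    # rank check: collinear sets have rank < 2 covariance
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise PoseError("source points are degenerate (collinear); "
                        "pose is not unique")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    xform = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((xform.apply(P) - Q) ** 2, axis=1))))
    return xform, rms


def _correspondence_points(spec, samples_per_tine: int = 12) -> np.ndarray:
    """Tip + arc-length-resampled tine points, in tine order."""
    pts = [np.atleast_2d(spec.tip_position)]
    for path in spec.tine_paths:
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        si = np.linspace(0.0, s[-1], samples_per_tine)
        pts.append(np.column_stack(
            [np.interp(si, s, path[:, k]) for k in range(3)]))
    return np.vstack(pts)


def pose_from_electrode(measured, ideal, samples_per_tine: int = 12):
    """Rigid transform carrying the ideal electrode onto the measured one.

    Both specs must have the same tine count and ordering; correspondence
    uses the tip plus arc-length-matched samples along each tine.  Returns
    (RigidTransform, rms_residual_mm).
    """
    if measured.n_tines != ideal.n_tines:
        raise PoseError(
            f"tine count mismatch: measured {measured.n_tines} vs "
            f"ideal {ideal.n_tines}")
    P = _correspondence_points(ideal, samples_per_tine)
    Q = _correspondence_points(measured, samples_per_tine)
    return kabsch(P, Q)
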