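"""Rigid-body transforms and rotation helpers (right-handed frames,
X anterior, Y superior, Z subject's-right; mm and degrees)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "rot_about_axis", "rotation_between",
           "pelvis_rotation", "hip_rotation"]


def pelvis_rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    """Pelvis orientation from its three rotation coordinates (deg)."""
    return Rotation.from_euler("xyz", [rx, ry, rz], degrees=True).as_matrix()


def hip_rotation(flexion: float, adduction: float, rotation: float) -> np.ndarray:
    """Hip ball-and-socket orientation (deg): flexion about +Z,
    adduction about -X (medial drift of the left limb), axial rotation
    about +Y."""
    return (Rotation.from_euler("z", flexion, degrees=True)
            * Rotation.from_euler("x", -adduction, degrees=True)
            * Rotation.from_euler("y", rotation, degrees=True)).as_matrix()


@dataclass(frozen=True)
class RigidTransform:
    """p -> R @ p + t with R a proper rotation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def rot_about_axis(axis, angle_deg: float, point=None) -> RigidTransform:
    """Rotation by ``angle_deg`` about a line through ``point`` (origin if
    omitted) with direction ``axis``."""
    d = np.asarray(axis, dtype=float)
    d = d / np.linalg.norm(d)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * d).as_matrix()
    if point is None:
        return RigidTransform(R, np.zeros(3))
    p = np.asarray(point, dtype=float)
    return RigidTransform(R, p - R @ p)


def rotation_between(a, b) -> np.ndarray:
    """Minimal rotation matrix mapping unit direction ``a`` onto ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    s = np.linalg.norm(v)
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * v / s).as_matrix()
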