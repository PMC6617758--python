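"""Least-squares geometric primitives for joint-axis estimation.

Joint centres and axes of the lower-limb model are derived from bone
point clouds: a sphere fitted to the femoral head gives the hip centre,
and cylinders fitted to the distal femoral condyles and the talar
trochlea give the knee and ankle hinge axes.  Muscle and ligament
attachments are mapped from an anatomical atlas onto the subject's bones
with a 12-parameter affine landmark registration.

All fits minimise geometric (orthogonal) distance: sphere and cylinder
fits start from a linear algebraic estimate and are refined with a
Gauss-Newton trust-region solver; the affine registration is a linear
least-squares problem solved exactly.

Units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateInputError, FitFailureError

__all__ = [
    "SphereFit",
    "CylinderFit",
    "AffineTransform",
    "fit_sphere",
    "fit_cylinder",
    "fit_affine",
    "apply_affine",
    "compose_affine",
]

#: convergence tolerance on the relative residual change
_FTOL = 1e-14
_MAX_ITER = 200


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: centre (mm), radius (mm), rms residual (mm)."""

    center: np.ndarray
    radius: float
    rms: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "radius": self.radius, "rms": self.rms}


@dataclass(frozen=True)
class CylinderFit:
    """Least-squares cylinder: a point on the axis, the unit axis
    direction (sign-normalised to positive Z, ties broken to positive X),
    the radius and the rms orthogonal residual, all in mm."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms: float

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float))
        d = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("axis direction must be a unit vector")
        object.__setattr__(self, "axis_direction", d)
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    def to_dict(self) -> dict:
        return {
            "axis_point": self.axis_point.tolist(),
            "axis_direction": self.axis_direction.tolist(),
            "radius": self.radius,
            "rms": self.rms,
        }


@dataclass(frozen=True)
class AffineTransform:
    """p -> A @ p + t with a non-singular 3x3 linear part A."""

    linear: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        A = np.asarray(self.linear, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(A)) <= 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {"linear": self.linear.tolist(), "translation": self.translation.tolist()}


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateInputError("expected an (n, 3) array of points")
    return pts


def _singular_values(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    return np.linalg.svd(centered, compute_uv=False)


def fit_sphere(points) -> SphereFit:
    """Fit a sphere by least squares (hip-centre estimation).

    An algebraic (linearised) solve provides the starting point, followed
    by Gauss-Newton refinement of the geometric radial residuals
    ``|p_i - c| - r``.  Requires at least 4 non-coplanar points.
    """
    pts = _as_points(points)
    if len(pts) < 4:
        raise DegenerateInputError("sphere fit needs at least 4 points")
    sv = _singular_values(pts)
    scale = max(sv[0], 1.0)
    if sv[-1] < 1e-9 * scale:
        raise DegenerateInputError("points are coplanar; sphere fit is degenerate")

    # algebraic fit: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.sum(pts**2, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    res = least_squares(resid, np.r_[c0, r0], method="lm", xtol=_FTOL,
                        ftol=_FTOL, gtol=_FTOL, max_nfev=_MAX_ITER * 5)
    c, r = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return SphereFit(center=c, radius=r, rms=rms)


def _normalize_axis_sign(d: np.ndarray) -> np.ndarray:
    if d[2] < 0 or (d[2] == 0 and d[0] < 0):
        return -d
    return d


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_cylinder(points, initial_axis=None) -> CylinderFit:
    """Fit an infinite circular cylinder by orthogonal least squares.

    Used for the distal femoral condyles (knee hinge), the talar trochlea
    (ankle hinge) and the posterior arc of the femoral component
    (post-operative hinge).  The axis is initialised from the principal
    axis of the point cloud unless ``initial_axis`` is given, then the
    five free parameters (two axis angles, two in-plane offsets of the
    axis point, radius) are refined on the orthogonal distance residuals.
    """
    pts = _as_points(points)
    if len(pts) < 6:
        raise DegenerateInputError("cylinder fit needs at least 6 points")
    sv = _singular_values(pts)
    scale = max(sv[0], 1.0)
    if sv[1] < 1e-9 * scale:
        raise DegenerateInputError("points are collinear; cylinder fit is degenerate")

    centroid = pts.mean(axis=0)
    if initial_axis is not None:
        d0 = np.asarray(initial_axis, dtype=float)
        d0 = d0 / np.linalg.norm(d0)
    else:
        centered = pts - centroid
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d0 = vt[0]
    theta0 = float(np.arccos(np.clip(d0[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(d0[1], d0[0]))

    def unpack(x):
        theta, phi, u, v, r = x
        d = _axis_from_angles(theta, phi)
        # orthonormal in-plane basis for the axis point offset
        helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        c = centroid + u * e1 + v * e2
        return c, d, r

    def resid(x):
        c, d, r = unpack(x)
        rel = pts - c
        radial = rel - np.outer(rel @ d, d)
        return np.linalg.norm(radial, axis=1) - r

    rel0 = pts - centroid
    radial0 = rel0 - np.outer(rel0 @ d0, d0)
    r0 = float(np.mean(np.linalg.norm(radial0, axis=1)))
    x0 = np.array([theta0, phi0, 0.0, 0.0, max(r0, 1e-6)])
    res = least_squares(resid, x0, method="lm", xtol=_FTOL, ftol=_FTOL,
                        gtol=_FTOL, max_nfev=_MAX_ITER * 10)
    if not res.success and np.sqrt(np.mean(res.fun**2)) > 1e-6 * scale:
        raise FitFailureError("cylinder fit did not converge", last_iterate=res.x)
    c, d, r = unpack(res.x)
    d = _normalize_axis_sign(d)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return CylinderFit(axis_point=c, axis_direction=d, radius=float(abs(r)), rms=rms)


def fit_affine(source, target) -> AffineTransform:
    """Least-squares 12-parameter affine registration of paired landmarks.

    Minimises ``sum_i |A s_i + t - g_i|^2`` over the 3x3 linear map ``A``
    and translation ``t``; needs >= 4 non-coplanar source landmarks.
    """
    src = _as_points(source)
    tgt = _as_points(target)
    if src.shape != tgt.shape:
        raise DegenerateInputError("source and target landmark counts differ")
    if len(src) < 4:
        raise DegenerateInputError("affine registration needs at least 4 pairs")
    sv = _singular_values(src)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("source landmarks are coplanar")

    M = np.hstack([src, np.ones((len(src), 1))])  # (n, 4)
    sol, *_ = np.linalg.lstsq(M, tgt, rcond=None)  # (4, 3)
    return AffineTransform(linear=sol[:3].T, translation=sol[3])


def apply_affine(transform: AffineTransform, points) -> np.ndarray:
    """Map points through ``A p + t``; accepts a single point or an (n,3) array."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ transform.linear.T + transform.translation
    return out[0] if single else out


def compose_affine(outer: AffineTransform, inner: AffineTransform) -> AffineTransform:
    """Composition ``outer . inner``: apply ``inner`` first."""
    return AffineTransform(
        linear=outer.linear @ inner.linear,
        translation=outer.linear @ inner.translation + outer.translation,
    )
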