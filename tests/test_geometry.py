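"""Least-squares primitive fitting and affine registration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tkabalance import (DegenerateInputError, apply_affine, compose_affine,
                        fit_affine, fit_cylinder, fit_sphere)
from tkabalance.geometry import AffineTransform


def _sphere_points(rng, center, radius, n, noise=0.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v + rng.normal(0, noise, (n, 3)) if noise else center + radius * v


class TestSphere:
    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        pts = _sphere_points(rng, np.array([10.0, -5.0, 3.0]), 25.0, 100)
        fit = fit_sphere(pts)
        assert np.allclose(fit.center, [10, -5, 3], atol=1e-9)
        assert abs(fit.radius - 25.0) < 1e-9
        assert fit.rms < 1e-9

    def test_noisy_recovery_monte_carlo(self):
        """Radius estimate unbiased to ~3 sigma/sqrt(n); rms tracks the
        injected noise level."""
        rng = np.random.default_rng(1)
        sigma, n, reps = 0.5, 1000, 30
        radii, rmss = [], []
        for _ in range(reps):
            pts = _sphere_points(rng, np.array([10.0, -5.0, 3.0]), 25.0, n,
                                 noise=sigma)
            fit = fit_sphere(pts)
            radii.append(fit.radius)
            rmss.append(fit.rms)
        # every replicate within 3 sigma/sqrt(n) of the true radius
        assert np.max(np.abs(np.array(radii) - 25.0)) < 3 * sigma / np.sqrt(n)
        # pooled mean limited by the O(sigma^2/r) curvature bias of
        # geometric sphere fits plus sampling error
        bias = sigma**2 / 25.0
        assert abs(np.mean(radii) - 25.0) < bias + 3 * sigma / np.sqrt(n * reps)
        assert abs(np.mean(rmss) - sigma) < 0.2 * sigma

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(DegenerateInputError):
            fit_sphere(pts)

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            fit_sphere(np.zeros((3, 3)))


def _cylinder_points(rng, axis_point, axis_dir, radius, n, half_len,
                     noise=0.0):
    d = np.asarray(axis_dir, float) / np.linalg.norm(axis_dir)
    helper = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    ang = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(-half_len, half_len, n)
    pts = (axis_point + radius * (np.outer(np.cos(ang), e1)
                                  + np.outer(np.sin(ang), e2)) + np.outer(z, d))
    return pts + rng.normal(0, noise, (n, 3)) if noise else pts


class TestCylinder:
    def test_exact_recovery(self):
        rng = np.random.default_rng(2)
        pts = _cylinder_points(rng, np.zeros(3), [0, 0, 1.0], 30.0, 200, 50.0)
        fit = fit_cylinder(pts)
        assert abs(fit.radius - 30.0) < 1e-8
        assert abs(abs(fit.axis_direction @ [0, 0, 1]) - 1) < 1e-8
        # axis passes through the origin
        rel = fit.axis_point - (fit.axis_point @ fit.axis_direction) * fit.axis_direction
        assert np.linalg.norm(rel) < 1e-6

    def test_axis_sign_normalized_to_positive_z(self):
        rng = np.random.default_rng(3)
        pts = _cylinder_points(rng, np.zeros(3), [0.1, 0.2, -0.97], 15.0, 150, 40.0)
        fit = fit_cylinder(pts)
        assert fit.axis_direction[2] > 0

    def test_generative_recovery_from_anatomy(self, anatomy):
        gen = anatomy.generative["condyle_cylinder"]
        fit = fit_cylinder(anatomy.condyle_cloud, initial_axis=[0, 0, 1])
        assert abs(fit.axis_direction @ gen["axis_direction"]) > 0.999
        assert abs(fit.radius - gen["radius"]) < 0.3
        assert abs(fit.rms - anatomy.generative["noise"]) < 0.2

    def test_collinear_rejected(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            fit_cylinder(pts)


class TestAffine:
    LANDMARKS = np.array([
        [0.0, 0, 0], [100, 0, 0], [0, 100, 0], [0, 0, 100],
        [50, 50, 0], [30, -20, 70],
    ])

    def test_identity(self):
        T = fit_affine(self.LANDMARKS, self.LANDMARKS)
        assert np.allclose(T.linear, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-10)

    def test_exact_recovery_of_known_affine(self):
        A = np.array([[1.2, 0.1, 0.0], [0.0, 0.9, 0.05], [0.02, 0.0, 1.1]])
        t = np.array([5.0, -3.0, 12.0])
        target = self.LANDMARKS @ A.T + t
        T = fit_affine(self.LANDMARKS, target)
        assert np.allclose(T.linear, A, atol=1e-10)
        assert np.allclose(T.translation, t, atol=1e-10)

    def test_noisy_residual_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-100, 100, (10, 3))
        A = np.array([[1.1, 0.2, 0], [0, 0.95, 0.1], [0.05, 0, 1.05]])
        tgt = src @ A.T + [1.0, 2.0, 3.0] + rng.normal(0, 1.0, (10, 3))
        T = fit_affine(src, tgt)
        # independent normal-equations solve
        M = np.hstack([src, np.ones((10, 1))])
        sol = np.linalg.solve(M.T @ M, M.T @ tgt)
        res_fit = np.linalg.norm(apply_affine(T, src) - tgt)
        res_oracle = np.linalg.norm(M @ sol - tgt)
        assert abs(res_fit - res_oracle) < 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            fit_affine(self.LANDMARKS[:3], self.LANDMARKS[:3])
        flat = self.LANDMARKS.copy()
        flat[:, 2] = 0.0
        with pytest.raises(DegenerateInputError):
            fit_affine(flat, flat)

    def test_apply_identity_and_translation(self):
        T = AffineTransform.identity()
        pts = np.array([[1.0, 2, 3], [-4, 5, 6]])
        assert np.allclose(apply_affine(T, pts), pts)
        T2 = AffineTransform(np.eye(3), [1.0, 2.0, 3.0])
        assert np.allclose(apply_affine(T2, np.zeros(3)), [1, 2, 3])

    def test_composition(self):
        rng = np.random.default_rng(5)
        T1 = AffineTransform(np.eye(3) + 0.1 * rng.normal(size=(3, 3)),
                             rng.normal(size=3))
        T2 = AffineTransform(np.eye(3) + 0.1 * rng.normal(size=(3, 3)),
                             rng.normal(size=3))
        p = rng.normal(size=(7, 3))
        lhs = apply_affine(T2, apply_affine(T1, p))
        rhs = apply_affine(compose_affine(T2, T1), p)
        assert np.allclose(lhs, rhs, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_exact_interpolation_property(self, seed):
        """Noiseless affine recovery is exact for any well-conditioned
        landmark set with >= 4 points."""
        rng = np.random.default_rng(seed)
        src = rng.uniform(-50, 50, (6, 3))
        sv = np.linalg.svd(src - src.mean(0), compute_uv=False)
        if sv[-1] < 1.0:
            return
        A = np.eye(3) + 0.2 * rng.normal(size=(3, 3))
        if abs(np.linalg.det(A)) < 0.1:
            return
        t = rng.normal(size=3)
        T = fit_affine(src, src @ A.T + t)
        assert np.allclose(T.linear, A, atol=1e-8)
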