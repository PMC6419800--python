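"""Solver tests: projections, prox, Douglas-Rachford fit, LLS baseline."""

import numpy as np
import pytest

from ellipsoidfit.design import PointCloud, build_design
from ellipsoidfit.quadrics import (
    PackedQuadric,
    geometry_to_quadric,
    packed_length,
    quadric_to_geometry,
    unpack,
)
from ellipsoidfit.solver import (
    SolverConfig,
    fit_ellipsoid,
    fit_ellipsoid_dr,
    fit_ellipsoid_lls,
    project_constraint,
    prox_objective,
)
from ellipsoidfit.synthetic import random_ellipsoid
from ellipsoidfit.whitening import apply_transform, compute_whitening

from conftest import instance_battery, make_instance
from _oracles import constrained_fit_pg, project_feasible


def _diag_quadric(diag, dim):
    m = packed_length(dim)
    v = np.zeros(m)
    v[:dim] = diag
    return PackedQuadric(dim=dim, coeffs=v)


class TestProjectConstraint:
    def test_interior_simplex_shift(self):
        q = _diag_quadric([0.5, 0.4, 0.3], 3)
        out = unpack(project_constraint(q))
        np.testing.assert_allclose(
            np.diag(out.matrix_part), np.array([0.5, 0.4, 0.3]) - 0.2 / 3, atol=1e-12
        )

    def test_single_active_coordinate(self):
        q = _diag_quadric([1.5, -0.2, -0.3], 3)
        out = unpack(project_constraint(q))
        np.testing.assert_allclose(np.diag(out.matrix_part), [1, 0, 0], atol=1e-12)

    def test_linear_and_constant_blocks_untouched(self, rng):
        v = rng.normal(size=10)
        out = project_constraint(PackedQuadric(dim=3, coeffs=v))
        np.testing.assert_array_equal(out.coeffs[6:], v[6:])

    @pytest.mark.parametrize("dim", [2, 3])
    def test_matches_bruteforce_kkt_enumeration(self, dim, rng):
        m = packed_length(dim)
        for _ in range(60):
            v = rng.normal(size=m) * rng.choice([0.1, 1, 10])
            ours = project_constraint(PackedQuadric(dim=dim, coeffs=v)).coeffs
            brute = project_feasible(v, dim)
            np.testing.assert_allclose(ours, brute, atol=1e-12)
        # feasibility: PSD and unit trace
        quad = unpack(project_constraint(PackedQuadric(dim=dim, coeffs=v)))
        lam = np.linalg.eigvalsh(quad.matrix_part)
        assert lam[0] >= -1e-12
        assert np.trace(quad.matrix_part) == pytest.approx(1.0, abs=1e-12)


class TestProxObjective:
    def test_zero_design_is_identity(self, rng):
        design = build_design(PointCloud(points=np.zeros((3, 2))))
        # only the constant row is nonzero; use literally zero matrix
        from ellipsoidfit.design import DesignMatrix

        design = DesignMatrix(dim=2, matrix=np.zeros((6, 3)))
        q = PackedQuadric(dim=2, coeffs=rng.normal(size=6))
        np.testing.assert_allclose(
            prox_objective(q, design, 1.0).coeffs, q.coeffs, atol=1e-15
        )

    def test_small_step_limit(self, rng):
        cloud = PointCloud(points=rng.uniform(-2, 2, (8, 2)))
        design = build_design(cloud)
        q = PackedQuadric(dim=2, coeffs=rng.normal(size=6))
        out = prox_objective(q, design, 1e-12).coeffs
        np.testing.assert_allclose(out, q.coeffs, atol=1e-8)

    def test_matches_direct_quadratic_minimization(self, rng):
        cloud = PointCloud(points=rng.uniform(-2, 2, (8, 3)))
        design = build_design(cloud)
        q = PackedQuadric(dim=3, coeffs=rng.normal(size=10))
        gamma = 0.37
        ours = prox_objective(q, design, gamma).coeffs
        # independent oracle: the prox is the least-squares problem
        # min || [D^T; I/sqrt(2 gamma)] p - [0; q/sqrt(2 gamma)] ||^2
        w = 1.0 / np.sqrt(2.0 * gamma)
        Astack = np.vstack([design.matrix.T, w * np.eye(10)])
        bstack = np.concatenate([np.zeros(design.n), w * q.coeffs])
        ref = np.linalg.lstsq(Astack, bstack, rcond=None)[0]
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestDouglasRachfordFit:
    def test_nine_noiseless_points_recover_3d_ellipsoid(self, rng):
        for trial in range(20):
            truth, cloud = make_instance(rng, 3, 9, 0.0, seed=trial)
            result = fit_ellipsoid(cloud)
            fitted = result.geometry()
            scale = truth.semilengths.mean()
            assert np.linalg.norm(fitted.center - truth.center) < 1e-6 * scale
            np.testing.assert_allclose(
                fitted.semilengths, truth.semilengths, rtol=1e-6
            )

    def test_symmetric_seven_point_unit_sphere(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
             [1 / np.sqrt(3)] * 3]
        )
        result = fit_ellipsoid_dr(PointCloud(points=pts))
        np.testing.assert_allclose(result.quadric.matrix_part, np.eye(3) / 3, atol=1e-9)
        assert result.quadric.scalar_part == pytest.approx(-1 / 3, abs=1e-9)

    def test_noiseless_2d_matches_convex_oracle(self, rng):
        truth, cloud = make_instance(rng, 2, 50, 0.0, seed=7)
        white = apply_transform(compute_whitening(cloud), cloud)
        result = fit_ellipsoid_dr(white)
        design = build_design(white)
        scale = np.trace(design.gram())
        assert result.final_objective < 1e-18 * scale
        q_pg, obj_pg = constrained_fit_pg(design.matrix, 2)
        assert abs(result.final_objective - obj_pg) <= 1e-8 * scale

    def test_feasibility_of_every_result(self):
        for truth, cloud in instance_battery(seed=1, trials=24):
            result = fit_ellipsoid(cloud)
            lam = np.linalg.eigvalsh(result.quadric.matrix_part)
            assert lam[0] >= -1e-10
            assert np.trace(result.quadric.matrix_part) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_objective_decreases_after_burn_in(self, rng):
        truth, cloud = make_instance(rng, 3, 40, 0.03, seed=3)
        tf = compute_whitening(cloud)
        white = apply_transform(tf, cloud)
        early = fit_ellipsoid_dr(white, SolverConfig(max_iterations=10))
        full = fit_ellipsoid_dr(white)
        assert full.final_objective <= early.final_objective * (1 + 1e-12)

    def test_exact_interpolation_with_many_points(self, rng):
        truth, cloud = make_instance(rng, 3, 2 * 10, 0.0, seed=11)
        tf = compute_whitening(cloud)
        result = fit_ellipsoid_dr(apply_transform(tf, cloud))
        design = build_design(apply_transform(tf, cloud))
        assert result.final_objective <= 1e-18 * np.trace(design.gram())

    def test_whitened_cloud_same_with_and_without_whitening(self, rng):
        truth, cloud = make_instance(rng, 3, 30, 0.01, seed=5)
        white = apply_transform(compute_whitening(cloud), cloud)
        direct = fit_ellipsoid_dr(white).geometry()
        via_pipeline = fit_ellipsoid(white).geometry()
        np.testing.assert_allclose(via_pipeline.center, direct.center, atol=1e-7)
        np.testing.assert_allclose(
            via_pipeline.semilengths, direct.semilengths, rtol=1e-7
        )


class TestCovariance:
    def test_rigid_motion_covariance(self, rng):
        for trial in range(10):
            truth, cloud = make_instance(rng, 3, 25, 0.02, seed=40 + trial)
            M = rng.normal(size=(3, 3))
            R, _ = np.linalg.qr(M)
            t = rng.uniform(-30, 30, 3)
            moved = PointCloud(points=cloud.points @ R.T + t)
            g1 = fit_ellipsoid(cloud).geometry()
            g2 = fit_ellipsoid(moved).geometry()
            np.testing.assert_allclose(g2.center, R @ g1.center + t, atol=1e-6)
            np.testing.assert_allclose(g2.semilengths, g1.semilengths, rtol=1e-6)

    def test_affine_covariance_with_whitening(self, rng):
        for trial in range(10):
            truth, cloud = make_instance(rng, 3, 25, 0.02, seed=60 + trial)
            M = rng.normal(size=(3, 3)) + 2 * np.eye(3)
            t = rng.uniform(-10, 10, 3)
            mapped = PointCloud(points=cloud.points @ M.T + t)
            g1 = fit_ellipsoid(cloud).geometry()
            g2 = fit_ellipsoid(mapped).geometry()
            # map g1 through the affine map and compare surface-wise:
            # the image of g1 has quadric pulled back through the inverse map
            from ellipsoidfit.whitening import WhitenTransform, pullback_quadric

            Minv = np.linalg.inv(M)
            tf = WhitenTransform(mean=t, forward_map=Minv, inverse_map=M)
            # y on image ellipsoid iff Minv (y - t) on g1
            quad_mapped = pullback_quadric(tf, geometry_to_quadric(g1))
            g1_mapped = quadric_to_geometry(quad_mapped)
            np.testing.assert_allclose(g2.center, g1_mapped.center, atol=1e-6)
            np.testing.assert_allclose(
                g2.semilengths, g1_mapped.semilengths, rtol=1e-6
            )


class TestLLSBaseline:
    def test_noiseless_ellipse_same_as_constrained_fit(self, rng):
        truth, cloud = make_instance(rng, 2, 30, 0.0, seed=9)
        g_lls = fit_ellipsoid_lls(cloud).geometry()
        g_dr = fit_ellipsoid(cloud).geometry()
        np.testing.assert_allclose(g_lls.center, g_dr.center, atol=1e-7)
        np.testing.assert_allclose(g_lls.semilengths, g_dr.semilengths, rtol=1e-7)

    def test_five_generic_2d_points_unique_conic(self, rng):
        truth, cloud = make_instance(rng, 2, 5, 0.0, seed=13)
        design = build_design(cloud)
        s = np.linalg.svd(design.matrix.T, compute_uv=False)
        # null space of the 5x6 system is exactly one-dimensional
        assert s[4] / s[0] > 1e-8
        result = fit_ellipsoid_lls(cloud)
        assert result.final_objective < 1e-16 * np.trace(design.gram())

    def test_noisy_partial_arc_robustness(self, rng):
        # constrained fit never leaves the elliptic cone; LLS does, and its
        # center error is worse in the median
        dr_err, lls_err, lls_bad = [], [], 0
        for trial in range(30):
            geom = random_ellipsoid(
                rng, dim=2, center_range=20, semilength_range=(5, 15),
                max_anisotropy=3,
            )
            th0 = rng.uniform(0, 2 * np.pi)
            th = th0 + rng.uniform(0, np.pi, 40)
            s, R, c = geom.semilengths, geom.axes, geom.center
            X = np.stack([s[0] * np.cos(th), s[1] * np.sin(th)], -1) @ R.T + c
            X = X + rng.normal(0, 0.05 * s.mean(), X.shape)
            cloud = PointCloud(points=X)
            rd = fit_ellipsoid(cloud)
            rl = fit_ellipsoid_lls(cloud)
            assert not rd.non_elliptic
            assert np.linalg.eigvalsh(rd.quadric.matrix_part)[0] >= -1e-10
            dr_err.append(np.linalg.norm(rd.geometry().center - geom.center))
            if rl.non_elliptic:
                lls_bad += 1
                lls_err.append(np.inf)
            else:
                lls_err.append(np.linalg.norm(rl.geometry().center - geom.center))
        assert np.median(dr_err) <= np.median(lls_err)
        assert lls_bad >= 1


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(step_size=-1.0)
    with pytest.raises(ValueError):
        SolverConfig(relaxation=2.0)
    with pytest.raises(ValueError):
        SolverConfig(max_iterations=0)
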