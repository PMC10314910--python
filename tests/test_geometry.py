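"""Axisymmetric geometry: tangent-angle series, quadrature, curvatures."""

import numpy as np
import pytest
from scipy.integrate import quad

from nemshell.geometry import (
    ShapeProfile,
    build_surface_grid,
    closure_residual,
    eval_theta,
    geodesic_curvature_parallels,
    integrate_profile,
    principal_curvatures,
    rescale_to_unit_area,
    surface_measures,
)


class TestEvalTheta:
    @pytest.mark.parametrize(
        "amps, s, expected",
        [
            (np.zeros(4), np.pi / 2, np.pi / 2),            # pure linear term
            ([0.3, 0, 0, 0], np.pi / 2, np.pi / 2 + 0.3),   # sin(pi/2) = 1
        ],
    )
    def test_pointwise_values(self, amps, s, expected):
        prof = ShapeProfile(np.pi, amps, np.pi)
        theta, _ = eval_theta(prof, np.array([s]))
        assert theta[0] == pytest.approx(expected, abs=1e-14)

    def test_boundary_values_exact(self):
        rng = np.random.default_rng(0)
        prof = ShapeProfile(np.pi, 0.3 * rng.standard_normal(12), 2.7)
        theta, _ = eval_theta(prof, np.array([0.0, prof.Ls]))
        assert theta[0] == 0.0
        assert theta[1] == pytest.approx(np.pi, abs=1e-12)

    def test_derivative_is_analytic(self, wavy_profile):
        s = np.linspace(0.0, wavy_profile.Ls, 301)
        _, dtheta = eval_theta(wavy_profile, s)
        h = 1e-6
        tp, _ = eval_theta(wavy_profile, s[1:-1] + h)
        tm, _ = eval_theta(wavy_profile, s[1:-1] - h)
        fd = (tp - tm) / (2 * h)
        np.testing.assert_allclose(dtheta[1:-1], fd, atol=1e-7)

    def test_rejects_out_of_range(self, sphere_profile):
        with pytest.raises(ValueError):
            eval_theta(sphere_profile, np.array([-0.1]))
        with pytest.raises(ValueError):
            eval_theta(sphere_profile, np.array([sphere_profile.Ls + 0.1]))


class TestIntegrateProfile:
    def test_unit_sphere_coordinates(self, sphere_profile):
        grid = integrate_profile(sphere_profile, 201)
        mid = 100  # s = pi/2
        assert grid.rho[mid] == pytest.approx(1.0, abs=1e-8)
        assert grid.z[-1] - grid.z[0] == pytest.approx(2.0, abs=1e-8)
        assert grid.rho[-1] == pytest.approx(0.0, abs=1e-8)
        assert grid.rho[0] == 0.0

    def test_refinement_oracle(self, wavy_profile):
        """Coarse-grid rho, z agree with a 10x finer quadrature to < 1e-4."""
        coarse = integrate_profile(wavy_profile, 101)
        fine = integrate_profile(wavy_profile, 1001)
        scale = np.max(np.abs(fine.rho))
        np.testing.assert_allclose(coarse.rho, fine.rho[::10], atol=1e-4 * scale)
        np.testing.assert_allclose(coarse.z, fine.z[::10], atol=1e-4 * scale)

    def test_self_intersection_flagged_not_clipped(self):
        # strong odd-mode kick drives rho negative mid-curve
        prof = ShapeProfile(np.pi, [2.5, 0, 0, 0], np.pi)
        grid = integrate_profile(prof, 201)
        assert grid.self_intersecting
        assert grid.rho.min() < 0  # values preserved, not clipped


class TestCurvatures:
    def test_unit_sphere_umbilic(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 201)
        np.testing.assert_allclose(grid.C1, 1.0, atol=1e-12)
        np.testing.assert_allclose(grid.C2, 1.0, atol=1e-6)

    def test_pole_limit_matches_near_pole_nodes(self, wavy_profile):
        """C2 at the pole is assigned C1; sin(theta)/rho approaches it."""
        grid = build_surface_grid(wavy_profile, 801)
        for pole, near in ((0, slice(1, 4)), (-1, slice(-4, -1))):
            limit = grid.C2[near].mean()
            assert grid.C2[pole] == pytest.approx(limit, rel=2e-2)

    def test_degenerate_rho_raises(self, sphere_profile):
        # a pinched neck: rho hits zero at a non-pole node
        grid = integrate_profile(sphere_profile, 201)
        grid.rho[100] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            principal_curvatures(grid)

    def test_dual_formula_oracle(self, wavy_profile):
        """H, K from (C1, C2) match the rho/z-derivative expressions.

        Independent route: Gaussian and mean curvature of a surface of
        revolution from finite differences of the profile coordinates.
        """
        grid = build_surface_grid(wavy_profile, 1601)
        s = grid.s_nodes
        rho_s = np.gradient(grid.rho, s, edge_order=2)
        z_s = np.gradient(grid.z, s, edge_order=2)
        rho_ss = np.gradient(rho_s, s, edge_order=2)
        z_ss = np.gradient(z_s, s, edge_order=2)
        g = rho_s**2 + z_s**2
        inner = slice(8, -8)
        with np.errstate(divide="ignore", invalid="ignore"):
            K_fd = -z_s * (z_s * rho_ss - z_ss * rho_s) / (grid.rho * g**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            H_fd = (grid.rho * (z_s * rho_ss - z_ss * rho_s) - z_s * g) / (
                grid.rho * g**1.5)
        np.testing.assert_allclose(K_fd[inner], grid.K[inner], rtol=1e-3,
                                   atol=1e-3)
        # the profile-derivative route yields the curvature SUM with the
        # inward-normal sign: -(C1 + C2) on the unit sphere
        np.testing.assert_allclose(-H_fd[inner], grid.C1[inner] + grid.C2[inner],
                                   rtol=1e-3, atol=1e-3)


class TestGeodesicCurvature:
    def test_sphere_closed_form(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 201)
        s = grid.s_nodes[1:-1]
        np.testing.assert_allclose(grid.kg2[1:-1], np.cos(s) / np.sin(s),
                                   atol=1e-6)
        assert grid.kg2[100] == pytest.approx(0.0, abs=1e-12)  # equator

    def test_cylinder_region_is_zero(self):
        from nemshell.fixtures import FixtureSpec, make_seed_profile

        prof = make_seed_profile(FixtureSpec("spherocylinder", v_target=0.6,
                                             n_modes=40))
        grid = build_surface_grid(prof, 401)
        mid = slice(180, 221)
        np.testing.assert_allclose(grid.kg2[mid], 0.0, atol=0.05)


class TestMeasuresAndClosure:
    def test_unit_sphere_measures(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 201)
        m = surface_measures(grid)
        assert m.area == pytest.approx(4 * np.pi, rel=1e-7)
        assert m.volume == pytest.approx(4 * np.pi / 3, rel=1e-7)
        assert m.reduced_volume == pytest.approx(1.0, abs=1e-7)

    def test_reduced_volume_refinement(self, wavy_profile):
        coarse = surface_measures(build_surface_grid(wavy_profile, 101))
        fine = surface_measures(build_surface_grid(wavy_profile, 1001))
        assert coarse.reduced_volume == pytest.approx(fine.reduced_volume,
                                                      abs=1e-4)

    def test_closure_sphere(self, sphere_profile):
        assert closure_residual(sphere_profile) == pytest.approx(0.0, abs=1e-10)

    def test_closure_equals_independent_quadrature(self, sphere_profile):
        amps = sphere_profile.amplitudes.copy()
        amps[0] += 0.1
        prof = sphere_profile.with_amplitudes(amps)
        res = closure_residual(prof, 801)
        oracle, _ = quad(
            lambda s: np.cos(eval_theta(prof, np.array([s]))[0][0]),
            0.0, prof.Ls)
        assert res != 0.0
        assert res == pytest.approx(oracle, abs=1e-8)

    def test_arclength_identity(self, wavy_profile):
        """rho_,s^2 + z_,s^2 = 1 by construction of the parameterization."""
        grid = build_surface_grid(wavy_profile, 401)
        rho_s = np.cos(grid.theta)
        z_s = np.sin(grid.theta)
        np.testing.assert_allclose(rho_s**2 + z_s**2, 1.0, atol=1e-12)

    def test_rescale_invariance(self, wavy_profile):
        """Measures are invariant under scaling followed by re-normalization."""
        m0 = surface_measures(build_surface_grid(
            rescale_to_unit_area(wavy_profile, 401), 401))
        stretched = ShapeProfile(np.pi, wavy_profile.amplitudes,
                                 3.7 * wavy_profile.Ls)
        m1 = surface_measures(build_surface_grid(
            rescale_to_unit_area(stretched, 401), 401))
        assert m0.area == pytest.approx(4 * np.pi, rel=1e-12)
        assert m1.area == pytest.approx(m0.area, rel=1e-12)
        assert m1.reduced_volume == pytest.approx(m0.reduced_volume, rel=1e-12)

    def test_near_unit_reduced_volume_is_spherical(self):
        """v -> 1 forces the sphere: tiny admissible perturbations keep the
        node-wise deviation from the spherical profile small."""
        amps = np.zeros(8)
        amps[1] = 1e-4
        prof = rescale_to_unit_area(ShapeProfile(np.pi, amps, np.pi), 401)
        grid = build_surface_grid(prof, 401)
        m = surface_measures(grid)
        assert m.reduced_volume > 1 - 1e-6
        dev = np.max(np.abs(grid.rho - np.sin(grid.s_nodes * np.pi / prof.Ls)))
        assert dev < 1e-3
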