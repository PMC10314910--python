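"""Nematic order fields, intrinsic elastic energy, defect detection."""

import numpy as np
import pytest

from nemshell.energy import ModelParams
from nemshell.fixtures import FixtureSpec, make_defect_texture, make_seed_profile, random_texture
from nemshell.geometry import build_surface_grid
from nemshell.nematic import (
    NematicTexture,
    detect_defects,
    gradient_energy_density,
    order_and_director,
    total_charge,
)


def smooth_texture(grid, k_s=1, k_phi=2, amp=0.3):
    """A smooth analytic (q0, qm) field for discretization oracles."""
    S, PHI = np.meshgrid(grid.s_nodes, grid.phi_nodes, indexing="ij")
    x = np.pi * S / grid.s_nodes[-1]
    q0 = amp * np.sin(x) ** 2 * np.cos(k_s * x) * np.cos(k_phi * PHI)
    qm = amp * np.sin(x) ** 2 * np.sin(k_phi * PHI + 0.7)
    return NematicTexture(q0, qm)


class TestOrderAndDirector:
    @pytest.mark.parametrize(
        "q0, qm, lam, eta",
        [(0.3, 0.0, 0.3, 0.0),        # director along the meridian
         (0.0, 0.3, 0.3, np.pi / 4)],  # sin(2 eta) = 1
    )
    def test_examples(self, q0, qm, lam, eta):
        tex = NematicTexture(np.full((3, 3), q0), np.full((3, 3), qm))
        lam_f, eta_f = order_and_director(tex)
        assert lam_f[0, 0] == pytest.approx(lam)
        assert eta_f[0, 0] == pytest.approx(eta)

    def test_defect_flagged_as_nan(self):
        tex = NematicTexture(np.zeros((2, 2)), np.zeros((2, 2)))
        lam, eta = order_and_director(tex)
        assert np.all(lam == 0.0)
        assert np.all(np.isnan(eta))


class TestGradientEnergy:
    def test_nonnegative_and_quadratic_scaling(self, sphere_grid):
        rng = np.random.default_rng(3)
        tex = random_texture((41, 41), 0.4, rng)
        f1 = gradient_energy_density(tex, sphere_grid)
        assert np.all(f1 >= 0.0)
        tex2 = NematicTexture(0.5 * tex.q0, 0.5 * tex.qm)
        f2 = gradient_energy_density(tex2, sphere_grid)
        np.testing.assert_allclose(f2, 0.25 * f1, rtol=1e-12, atol=1e-15)

    def test_uniform_texture_on_cylinder_region(self):
        """On a cylindrical wall (kg2 = 0) a uniform texture costs nothing."""
        prof = make_seed_profile(FixtureSpec("spherocylinder", v_target=0.6,
                                             n_modes=40))
        grid = build_surface_grid(prof, 401, 31)
        tex = NematicTexture(np.full((401, 31), 0.25), np.full((401, 31), 0.3))
        f = gradient_energy_density(tex, grid)
        mid = slice(185, 216)
        assert np.abs(f[mid]).max() < 1e-2
        assert f.min() >= 0.0

    def test_global_gauge_invariance(self, sphere_grid):
        """Rotating (q0, qm) by a constant angle (a global director rotation
        by half that angle) leaves the elastic density unchanged."""
        tex = smooth_texture(sphere_grid)
        chi = 0.73
        c, s = np.cos(chi), np.sin(chi)
        rot = NematicTexture(c * tex.q0 - s * tex.qm, s * tex.q0 + c * tex.qm)
        f0 = gradient_energy_density(tex, sphere_grid)
        f1 = gradient_energy_density(rot, sphere_grid)
        np.testing.assert_allclose(f1, f0, rtol=1e-10, atol=1e-13)

    def test_mismatched_dimensions_rejected(self, sphere_grid):
        tex = NematicTexture(np.zeros((21, 41)), np.zeros((21, 41)))
        with pytest.raises(ValueError):
            gradient_energy_density(tex, sphere_grid)

    @staticmethod
    def _embedding_rel_error(sphere_profile, n):
        grid = build_surface_grid(sphere_profile, n, n)
        tex = smooth_texture(grid)
        f = gradient_energy_density(tex, grid, ki=1.0)

        phi = grid.phi_nodes
        theta = grid.theta
        ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
        cp, sp = np.cos(phi)[None, :], np.sin(phi)[None, :]
        e1 = np.stack([ct * cp, ct * sp, st * np.ones_like(cp)], axis=-1)
        e2 = np.stack([-sp * np.ones_like(ct), cp * np.ones_like(ct),
                       np.zeros((n, n))], axis=-1)
        nv = np.cross(e1, e2)
        q0 = tex.q0[..., None, None]
        qm = tex.qm[..., None, None]
        outer = lambda a, b: a[..., :, None] * b[..., None, :]
        Q = (q0 * (outer(e1, e1) - outer(e2, e2))
             + qm * (outer(e1, e2) + outer(e2, e1)))

        ds, dphi = grid.ds, grid.dphi
        dQ_s = np.gradient(Q, ds, axis=0, edge_order=2)
        dQ_p = (np.roll(Q, -1, axis=1) - np.roll(Q, 1, axis=1)) / (2 * dphi)
        dQ_p = dQ_p / np.where(grid.rho > 1e-12, grid.rho, np.inf)[:, None, None, None]
        P = np.eye(3) - outer(nv, nv)
        f_oracle = np.zeros((n, n))
        for dQ in (dQ_s, dQ_p):
            T = np.einsum("...ab,...bc,...cd->...ad", P, dQ, P)
            f_oracle += 0.5 * np.einsum("...ab,...ab->...", T, T)

        w = (grid.w_s * np.maximum(grid.J, 0.0))[:, None]
        F = float((w * f).sum() * dphi)
        F_oracle = float((w * f_oracle).sum() * dphi)
        return abs(F - F_oracle) / F_oracle

    def test_embedding_oracle(self, sphere_profile):
        """The (q0, qm) covariant expansion matches a brute-force oracle:
        embed Q as an ambient 3x3 tensor field, finite-difference it along
        the surface directions, project tangentially, and take the squared
        norm.  Integrated agreement reaches <1% under refinement."""
        rels = [self._embedding_rel_error(sphere_profile, n)
                for n in (41, 81, 161)]
        assert rels[2] < rels[1] < rels[0]  # second-order convergence
        assert rels[2] < 0.01               # ~0.4% at 161x161


class TestDefectDetection:
    def test_four_half_defects_roundtrip(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 61, 61)
        Ls = sphere_profile.Ls
        placed = [(0.45 * Ls, 0.1, 0.5), (0.55 * Ls, np.pi / 2 + 0.13, 0.5),
                  (0.45 * Ls, np.pi + 0.07, 0.5), (0.55 * Ls, 4.7, 0.5)]
        tex = make_defect_texture(grid, placed, 0.5)
        found = detect_defects(tex, grid, lam0=0.5)
        cores = [d for d in found if d.m != 0]
        assert len(cores) == 4
        assert all(d.m == 0.5 for d in cores)
        assert total_charge(found) == 2.0
        # positions recovered within one grid cell
        cell = max(grid.ds, grid.dphi)
        for s_k, phi_k, _ in placed:
            dist = min(
                np.hypot(d.s - s_k, np.sin(0.5 * (d.phi - phi_k)) * 2)
                for d in cores)
            assert dist < 1.5 * cell

    def test_pole_defects(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 61, 61)
        Ls = sphere_profile.Ls
        tex = make_defect_texture(grid, [(0.0, 0.0, 1.0), (Ls, 0.0, 1.0)], 0.5)
        found = detect_defects(tex, grid, lam0=0.5)
        assert sorted(d.m for d in found) == [1.0, 1.0]
        assert {d.kind for d in found} == {"pole"}

    def test_mixed_charges_total_two(self, sphere_profile):
        grid = build_surface_grid(sphere_profile, 61, 61)
        Ls = sphere_profile.Ls
        placed = [(0.2 * Ls, 0.5, 0.5), (0.2 * Ls, np.pi + 0.5, 0.5),
                  (0.6 * Ls, 0.3, 0.5), (0.6 * Ls, 2.0, -0.5),
                  (0.6 * Ls, 3.5, 0.5), (0.6 * Ls, 5.2, -0.5),
                  (Ls, 0.0, 1.0)]
        tex = make_defect_texture(grid, placed, 0.5)
        found = detect_defects(tex, grid, lam0=0.5)
        assert total_charge(found) == 2.0
        ms = sorted(d.m for d in found)
        assert ms == [-0.5, -0.5, 0.5, 0.5, 0.5, 0.5, 1.0]

    def test_charge_two_for_arbitrary_textures(self, sphere_grid):
        """Poincare-Hopf: any texture on the closed shell carries total
        winding 2, including completely random ones."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tex = random_texture((41, 41), 0.45, rng)
            found = detect_defects(tex, sphere_grid, lam0=0.5)
            assert total_charge(found) == 2.0

    def test_nested_loop_oracle(self, sphere_profile):
        """Brute-force winding on three nested index loops around a core
        agrees with the reported charge."""
        grid = build_surface_grid(sphere_profile, 61, 61)
        Ls = sphere_profile.Ls
        tex = make_defect_texture(
            grid, [(0.5 * Ls, np.pi, 0.5), (0.3 * Ls, 0.0, 0.5),
                   (0.0, 0.0, 0.5), (Ls, 0.0, 0.5)], 0.5)
        found = detect_defects(tex, grid, lam0=0.5)
        target = [d for d in found
                  if d.kind == "interior" and abs(d.s - 0.5 * Ls) < 0.1]
        assert len(target) == 1
        i0 = int(round(0.5 * (target[0].rows[0] + target[0].rows[1])))
        j0 = int(round(target[0].phi / grid.dphi))
        two_eta = np.arctan2(tex.qm, tex.q0)

        def loop_winding(r):
            path = []
            for j in range(j0 - r, j0 + r + 1):
                path.append((i0 - r, j))
            for i in range(i0 - r, i0 + r + 1):
                path.append((i, j0 + r))
            for j in range(j0 + r, j0 - r - 1, -1):
                path.append((i0 + r, j))
            for i in range(i0 + r, i0 - r - 1, -1):
                path.append((i, j0 - r))
            vals = np.array([two_eta[i, j % 61] for i, j in path])
            steps = np.diff(np.concatenate([vals, vals[:1]]))
            steps = (steps + np.pi) % (2 * np.pi) - np.pi
            return -steps.sum() / (4 * np.pi)

        winds = [loop_winding(r) for r in (2, 3, 4)]
        assert all(w == pytest.approx(target[0].m, abs=1e-9) for w in winds)


class TestTotalCharge:
    def test_sums(self):
        from nemshell.nematic import Defect, DefectSet

        def ds_of(ms):
            return DefectSet([Defect(0, 0, m, (0, 0)) for m in ms])

        assert total_charge(ds_of([1, 1])) == 2
        assert total_charge(ds_of([0.5] * 4)) == 2
        assert total_charge(ds_of([0.5, 0.5, -0.5, -0.5, 0.5, 0.5, 1.0])) == 2
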