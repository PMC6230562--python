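"""Shell finite elements: element matrices, nonlinear solves, reactions,
deformed-geometry measurement."""

import numpy as np
import pytest

from stomech import synth
from stomech.meshing import ShellMesh, assign_material_frames
from stomech.shellfem import (
    LoadCase,
    OrthotropicMaterial,
    SimulationResult,
    SolverSettings,
    element_stiffness,
    hinge_bending_stiffness,
    measure_model_geometry,
    solve_nonlinear,
)

TRI = np.array([[0.0, 0.0, 0.0], [2.0, 0.1, 0.0], [0.3, 1.5, 0.0]])


class TestMaterial:
    def test_extreme_anisotropy_violates_symmetry(self):
        """A fixed major Poisson ratio with a 10⁶ stiffness contrast makes
        the completed compliance indefinite (physically impossible set)."""
        ok = OrthotropicMaterial(200.0, 200.0, 200.0, 33, 33, 33)
        assert ok.is_positive_definite()
        bad = OrthotropicMaterial(0.2, 200000.0, 0.2, 33, 33, 33)
        assert not bad.is_positive_definite()

    def test_plane_stress_isotropic_limit(self):
        E, nu = 120.0, 0.3
        Q = OrthotropicMaterial.isotropic(E, nu).plane_stress_Q()
        expect = E / (1 - nu**2) * np.array(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
        np.testing.assert_allclose(Q, expect, rtol=1e-12)

    def test_moduli_positive_required(self):
        with pytest.raises(ValueError):
            OrthotropicMaterial(-1, 1, 1, 1, 1, 1)


class TestElementStiffness:
    def test_rigid_body_modes_and_rank(self):
        """Symmetric PSD with exactly six zero-energy modes (rigid motions
        and out-of-plane bending, which lives on the hinges)."""
        mat = OrthotropicMaterial(99, 601, 601, 33, 33, 33)
        K = element_stiffness(TRI, mat, 0.5)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        w = np.linalg.eigvalsh(K)
        assert np.all(w > -1e-9 * abs(w[-1]))
        assert np.sum(np.abs(w) < 1e-9 * abs(w[-1])) == 6
        # rigid translation produces zero force
        u = np.tile([0.3, -0.2, 0.7], 3)
        assert np.abs(K @ u).max() < 1e-9 * np.abs(K).max()

    def test_isotropic_limit_matches_independent_cst(self):
        """In the isotropic limit the element matrix equals the classical
        plane-stress CST stiffness assembled independently."""
        E, nu = 100.0, 0.25
        t = 0.5
        mat = OrthotropicMaterial.isotropic(E, nu)
        K = element_stiffness(TRI, mat, t)

        # independent CST: 2D B-matrix from nodal coordinate differences
        e1 = TRI[1] - TRI[0]
        e2 = TRI[2] - TRI[0]
        n = np.cross(e1, e2)
        A = 0.5 * np.linalg.norm(n)
        a1 = e1 / np.linalg.norm(e1)
        a2 = np.cross(n / np.linalg.norm(n), a1)
        xy = np.stack([TRI @ a1, TRI @ a2], axis=1)
        (x1, y1), (x2, y2), (x3, y3) = xy
        b = np.array([y2 - y3, y3 - y1, y1 - y2])
        c = np.array([x3 - x2, x1 - x3, x2 - x1])
        B = np.zeros((3, 6))
        B[0, 0::2] = b
        B[1, 1::2] = c
        B[2, 0::2] = c
        B[2, 1::2] = b
        B /= 2 * A
        D = E / (1 - nu**2) * np.array(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
        K6 = t * A * B.T @ D @ B
        T = np.zeros((6, 9))
        for node in range(3):
            T[2 * node, 3 * node:3 * node + 3] = a1
            T[2 * node + 1, 3 * node:3 * node + 3] = a2
        K_ref = T.T @ K6 @ T
        np.testing.assert_allclose(K, K_ref, rtol=0, atol=1e-8 * np.abs(K_ref).max())

    def test_thickness_scaling_membrane_linear_bending_cubic(self):
        mat = OrthotropicMaterial(99, 601, 601, 33, 33, 33)
        K1 = element_stiffness(TRI, mat, 0.5)
        K2 = element_stiffness(TRI, mat, 1.0)
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-12)
        b1 = hinge_bending_stiffness(mat, 0.5, edge_len=1.0, area_sum=1.0)
        b2 = hinge_bending_stiffness(mat, 1.0, edge_len=1.0, area_sum=1.0)
        assert b2 == pytest.approx(8.0 * b1, rel=1e-12)

    def test_zero_area_rejected(self):
        mat = OrthotropicMaterial.isotropic(100.0)
        degenerate = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="area"):
            element_stiffness(degenerate, mat, 0.5)


class TestSolver:
    def test_zero_turgor_zero_displacement(self, col0_mesh_coarse,
                                           wildtype_wall_material):
        res = solve_nonlinear(col0_mesh_coarse, wildtype_wall_material,
                              LoadCase(turgor=0.0),
                              SolverSettings(n_increments=1), measure=False)
        assert res.converged
        assert np.abs(res.displacements).max() < 1e-9

    def test_pressurized_sphere_matches_closed_form(self, sphere_mesh):
        """Thin-sphere linear oracle: Δr = pR²(1−ν)/(2tE) within 3%."""
        E, nu, p, R, t = 100.0, 0.003, 0.01, 10.0, 0.5
        res = solve_nonlinear(sphere_mesh, OrthotropicMaterial.isotropic(E, nu),
                              LoadCase(turgor=p),
                              SolverSettings(n_increments=1), measure=False)
        assert res.converged
        x = sphere_mesh.nodes + res.displacements
        x -= x.mean(axis=0)
        dr = np.linalg.norm(x, axis=1).mean() - R
        expected = p * R**2 * (1 - nu) / (2 * t * E)
        assert dr == pytest.approx(expected, rel=0.03)

    def test_energy_consistency_linear_regime(self, sphere_mesh):
        res = solve_nonlinear(sphere_mesh, OrthotropicMaterial.isotropic(100.0),
                              LoadCase(turgor=0.01),
                              SolverSettings(n_increments=1), measure=False)
        assert res.external_work == pytest.approx(2 * res.strain_energy
                                                  - res.external_work, rel=0.02)
        assert res.strain_energy == pytest.approx(res.external_work, rel=0.01)

    def test_mirror_symmetry(self, col0_closed, wildtype_wall_material):
        """A y-mirror-symmetric mesh and load give mirror-symmetric
        displacements."""
        mesh = synth.generate_torus_complex(col0_closed, (16, 12))
        res = solve_nonlinear(mesh, wildtype_wall_material, LoadCase(turgor=2.0),
                              SolverSettings(n_increments=4), measure=False)
        assert res.converged
        # match nodes to their y-mirror images; compare deformed shapes
        # modulo the rigid motion fixed by the (arbitrary) 3-2-1 support
        from scipy.spatial import cKDTree

        mirrored = mesh.nodes * np.array([1.0, -1.0, 1.0])
        dist, pair = cKDTree(mesh.nodes).query(mirrored)
        assert dist.max() < 1e-8
        x = mesh.nodes + res.displacements
        x_m = x[pair] * np.array([1.0, -1.0, 1.0])
        a = x - x.mean(axis=0)
        b = x_m - x_m.mean(axis=0)
        U, _, Vt = np.linalg.svd(a.T @ b)
        Rot = (U @ Vt).T
        resid = np.abs(a @ Rot.T - b).max()
        assert resid < 2e-3 * np.abs(res.displacements).max()

    def test_stiffer_walls_open_less(self, col0_closed):
        mesh = synth.generate_torus_complex(col0_closed, (16, 12))
        soft = OrthotropicMaterial(99, 601, 601, 33, 33, 33)
        stiff = OrthotropicMaterial(990, 6010, 6010, 330, 330, 330)
        r1 = solve_nonlinear(mesh, soft, LoadCase(turgor=5.0),
                             SolverSettings(n_increments=6))
        r2 = solve_nonlinear(mesh, stiff, LoadCase(turgor=5.0),
                             SolverSettings(n_increments=6))
        d1 = r1.deformed_geometry.pore_width - 1.2
        d2 = r2.deformed_geometry.pore_width - 1.2
        assert d2 < d1

    def test_mesh_convergence_pore_width(self, col0_closed, wildtype_wall_material):
        """Halving the element size changes the final pore width by <2%."""
        lc, st = LoadCase(turgor=5.0), SolverSettings(n_increments=8)
        r1 = solve_nonlinear(synth.generate_torus_complex(col0_closed, (32, 24)),
                             wildtype_wall_material, lc, st)
        r2 = solve_nonlinear(synth.generate_torus_complex(col0_closed, (64, 48)),
                             wildtype_wall_material, lc, st)
        assert r2.deformed_geometry.pore_width == pytest.approx(
            r1.deformed_geometry.pore_width, rel=0.02)


class TestReactions:
    def test_unconstrained_loadings_zero(self, col0_mesh_coarse,
                                         wildtype_wall_material):
        res = solve_nonlinear(col0_mesh_coarse, wildtype_wall_material,
                              LoadCase(turgor=1.0),
                              SolverSettings(n_increments=2), measure=False)
        assert res.junction_loading == 0.0
        assert res.dorsal_loading == 0.0
        # statically determinate support: reactions vanish for balanced load
        assert np.abs(res.reactions).max() < 1e-5

    def test_hemisphere_equatorial_reaction_balances_pressure(self):
        """Fixed-equator hemisphere under p: net reaction = p·πR² within 2%."""
        import trimesh

        R, p = 10.0, 0.05
        ico = trimesh.creation.icosphere(subdivisions=3, radius=R)
        keep = np.asarray(ico.faces)[
            np.asarray(ico.vertices)[np.asarray(ico.faces)][:, :, 2].min(axis=1)
            >= -1e-9]
        used = np.unique(keep)
        remap = -np.ones(len(ico.vertices), dtype=int)
        remap[used] = np.arange(len(used))
        mesh = ShellMesh(nodes=np.asarray(ico.vertices)[used],
                         triangles=remap[keep],
                         thickness=np.full(len(keep), 0.5))
        assign_material_frames(mesh)
        equator = np.where(np.abs(mesh.nodes[:, 2]) < 1e-6)[0]
        res = solve_nonlinear(mesh, OrthotropicMaterial.isotropic(500.0),
                              LoadCase(turgor=p),
                              SolverSettings(n_increments=2), measure=False,
                              fixed_nodes=equator)
        assert res.converged
        net = res.reactions.sum(axis=0)
        assert abs(net[2]) == pytest.approx(p * np.pi * R**2, rel=0.02)

    def test_constraint_reaction_sign_flips_with_target(self, col0_closed,
                                                        wildtype_wall_material):
        mesh = synth.generate_torus_complex(col0_closed, (16, 12))
        st = SolverSettings(n_increments=5)
        out = solve_nonlinear(mesh, wildtype_wall_material,
                              LoadCase(turgor=0.0, constraint_mode="complex-dims",
                                       target_complex_length=25.5,
                                       target_complex_width=15.8),
                              st, measure=False)
        inward = solve_nonlinear(mesh, wildtype_wall_material,
                                 LoadCase(turgor=0.0, constraint_mode="complex-dims",
                                          target_complex_length=23.5,
                                          target_complex_width=13.8),
                                 st, measure=False)
        assert out.converged and inward.converged
        assert np.sign(out.dorsal_loading) == -np.sign(inward.dorsal_loading)

    def test_complex_dims_requires_targets(self):
        with pytest.raises(ValueError, match="target"):
            LoadCase(constraint_mode="complex-dims")


class TestMeasureModelGeometry:
    def _zero_result(self, mesh):
        return SimulationResult(
            displacements=np.zeros_like(mesh.nodes), converged=True,
            increments_completed=1)

    def test_undeformed_torus_returns_construction_dims(self, col0_mesh_coarse):
        geo = measure_model_geometry(self._zero_result(col0_mesh_coarse),
                                     col0_mesh_coarse)
        assert geo.pore_width == pytest.approx(1.2, abs=1e-9)
        assert geo.pore_length == pytest.approx(11.9, abs=1e-9)
        assert geo.complex_length == pytest.approx(24.5, abs=1e-9)
        assert geo.complex_width == pytest.approx(14.8, abs=1e-9)

    def test_pore_area_matches_shoelace(self, col0_mesh_coarse):
        geo = measure_model_geometry(self._zero_result(col0_mesh_coarse),
                                     col0_mesh_coarse)
        rim = col0_mesh_coarse.nodes[
            col0_mesh_coarse.node_sets["pore_rim"]][:, :2]
        x, y = rim[:, 0], rim[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1))
                             - np.dot(y, np.roll(x, -1)))
        assert geo.pore_area == pytest.approx(shoelace, rel=1e-9)

    def test_sphere_has_no_pore_but_correct_extents(self, sphere_mesh):
        geo = measure_model_geometry(self._zero_result(sphere_mesh),
                                     sphere_mesh)
        assert geo.pore_width is None
        assert geo.complex_length == pytest.approx(20.0, rel=0.01)

    def test_non_converged_result_rejected(self, col0_mesh_coarse):
        bad = SimulationResult(
            displacements=np.zeros_like(col0_mesh_coarse.nodes),
            converged=False, increments_completed=0)
        with pytest.raises(ValueError, match="converged"):
            measure_model_geometry(bad, col0_mesh_coarse)
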