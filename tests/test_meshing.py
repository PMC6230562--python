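"""Ring splines, tube triangulation, regions/thickness/frames, I/O."""

import numpy as np
import pytest

from stomech import synth
from stomech.meshing import (
    LandmarkSet,
    ThicknessTable,
    assign_material_frames,
    assign_regions_and_thickness,
    eval_ring_spline,
    export_landmarks,
    export_mesh,
    fit_ring_splines,
    import_landmarks,
    import_mesh,
    landmarks_to_mesh,
    resample_and_triangulate,
    triangulate_ring_grid,
    REGIONS,
)


def _circle_rings(n_rings=5, n_pts=12, radius=3.0, height=10.0, jitter=0.0,
                  seed=0):
    rng = np.random.default_rng(seed)
    rings = []
    th = 2 * np.pi * np.arange(n_pts) / n_pts
    for i in range(n_rings):
        z = height * i / (n_rings - 1)
        ring = np.stack([radius * np.cos(th), radius * np.sin(th),
                         np.full(n_pts, z)], axis=1)
        rings.append(ring + rng.normal(0, jitter, ring.shape))
    return rings


class TestRingSplines:
    def test_interpolates_exact_circle(self):
        ring = _circle_rings(n_rings=2)[0]
        sp = fit_ring_splines(ring, smoothing=0.0)
        # with zero smoothing the spline interpolates the inputs exactly
        at_knots = eval_ring_spline(sp, sp.u_fit)
        assert np.allclose(at_knots, ring, atol=1e-6)
        # and stays near the circle between knots
        pts = eval_ring_spline(sp, np.linspace(0, 1, 200, endpoint=False))
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert np.abs(r - 3.0).max() < 0.05

    def test_smoothing_reduces_curvature_variance(self):
        ring = _circle_rings(jitter=0.15, seed=3)[0]
        u = np.linspace(0, 1, 360, endpoint=False)

        def curv_var(tck):
            pts = eval_ring_spline(tck, u)
            d1 = np.gradient(pts, axis=0)
            d2 = np.gradient(d1, axis=0)
            k = np.linalg.norm(np.cross(d1, d2), axis=1) / (
                np.linalg.norm(d1, axis=1) ** 3 + 1e-12)
            return np.var(k)

        v0 = curv_var(fit_ring_splines(ring, smoothing=0.0))
        v1 = curv_var(fit_ring_splines(ring, smoothing=1.0))
        assert v1 < v0

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(ValueError):
            fit_ring_splines(np.zeros((3, 3)))
        line = np.stack([np.linspace(0, 1, 8), np.zeros(8), np.zeros(8)], axis=1)
        with pytest.raises(ValueError, match="degenerate|colinear"):
            fit_ring_splines(line)


class TestTriangulation:
    def test_strip_count_two_rings(self):
        splines = [fit_ring_splines(r) for r in _circle_rings(n_rings=2)]
        mesh = resample_and_triangulate(splines, 8)
        assert len(mesh.triangles) == 16  # 2·n per strip

    def test_cylinder_lateral_area(self):
        splines = [fit_ring_splines(r) for r in _circle_rings(n_rings=9)]
        mesh = resample_and_triangulate(splines, 64)
        assert mesh.total_area == pytest.approx(2 * np.pi * 3.0 * 10.0, rel=0.02)

    def test_start_index_rotation_leaves_shape_unchanged(self):
        """Minimal-twist correspondence: rotating one ring's start index
        must not twist the tube (vertex sets stay within an element size)."""
        rings = _circle_rings(n_rings=4)
        rotated = [np.roll(r, 5, axis=0) if i == 2 else r
                   for i, r in enumerate(rings)]
        m1 = resample_and_triangulate([fit_ring_splines(r) for r in rings], 24)
        m2 = resample_and_triangulate([fit_ring_splines(r) for r in rotated], 24)
        from scipy.spatial import cKDTree

        d12 = cKDTree(m1.nodes).query(m2.nodes)[0].max()
        elem = np.sqrt(m1.areas().mean() * 2)
        assert d12 < elem

    def test_folded_sweep_rejected(self):
        rings = _circle_rings(n_rings=4)
        rings[2][:, 2] = -5.0  # sweep reverses direction
        with pytest.raises(ValueError, match="self-intersecting"):
            resample_and_triangulate([fit_ring_splines(r) for r in rings], 16)

    def test_closed_tube_euler_characteristic(self, col0_closed):
        # closed sweep (torus topology) → χ = 0
        closed = synth.generate_torus_complex(col0_closed, (16, 12))
        assert closed.euler_characteristic() == 0
        # open cylinder with fan caps (sphere topology) → χ = 2
        grid = np.array(_circle_rings(n_rings=6))
        capped = triangulate_ring_grid(grid, cap_ends=True)
        assert capped.euler_characteristic() == 2
        assert capped.is_watertight()

    def test_refinement_convergence(self, col0_closed):
        """Doubling the resolution changes measured dimensions by <1%."""
        from stomech.synth import generate_torus_complex, measure_mesh_dimensions

        d1 = measure_mesh_dimensions(generate_torus_complex(col0_closed, (24, 16)))
        d2 = measure_mesh_dimensions(generate_torus_complex(col0_closed, (48, 32)))
        for k in d1:
            assert d2[k] == pytest.approx(d1[k], rel=0.01)


class TestRegionsAndThickness:
    def test_uniform_table(self, col0_closed):
        mesh = synth.generate_torus_complex(
            col0_closed, (24, 16), thickness_table=ThicknessTable.uniform(0.5))
        assert np.allclose(mesh.thickness, 0.5)

    def test_ventral_doubling_is_local(self, col0_closed):
        mesh = synth.generate_torus_complex(col0_closed, (24, 16))
        base = ThicknessTable.uniform(0.5)
        doubled = ThicknessTable({**base.thickness, "ventral": 1.0})
        m2 = mesh.copy()
        assign_regions_and_thickness(m2, doubled)
        changed = ~np.isclose(m2.thickness, mesh.thickness)
        assert np.all(mesh.region[changed] == "ventral")
        assert np.all(m2.thickness[~changed] == mesh.thickness[~changed])

    def test_regions_partition_area(self, col0_mesh_coarse):
        areas = col0_mesh_coarse.areas()
        per_region = sum(areas[col0_mesh_coarse.region == r].sum()
                         for r in REGIONS)
        assert per_region == pytest.approx(areas.sum(), rel=1e-12)

    def test_missing_region_raises(self, col0_closed):
        mesh = synth.generate_torus_complex(col0_closed, (24, 16))
        with pytest.raises(Exception, match="ventral"):
            assign_regions_and_thickness(
                mesh, ThicknessTable({"dorsal": 0.5, "upper periclinal": 0.5,
                                      "upper periclinal ledge": 0.5,
                                      "lower periclinal": 0.5}))

    def test_thickness_bounds_validated(self):
        with pytest.raises(ValueError):
            ThicknessTable({"ventral": 10.0})


class TestFrames:
    def test_cylinder_hoop_perpendicular_to_axis(self):
        splines = [fit_ring_splines(r) for r in _circle_rings(n_rings=9)]
        mesh = resample_and_triangulate(splines, 32)
        assign_material_frames(mesh)
        # e2 (hoop) ⊥ cylinder axis (z)
        assert np.abs(mesh.frame[:, 1, 2]).max() < 1e-6

    def test_torus_longitudinal_tangent(self):
        """On a circular-centerline torus every sweep parallel is a circle,
        so e1 must be azimuthal (tangent to the centerline circle) within 2°."""
        params = synth.ParametricComplex(
            pore_width=6.0, pore_length=6.0, complex_length=20.0,
            complex_width=20.0, guard_cell_width=5.0)
        mesh = synth.generate_torus_complex(params, (48, 24))
        cent = mesh.centroids()
        phi = np.arctan2(cent[:, 1], cent[:, 0])
        tang = np.stack([-np.sin(phi), np.cos(phi), np.zeros(len(phi))], axis=1)
        cosang = np.abs(np.einsum("ij,ij->i", mesh.frame[:, 0], tang))
        assert np.degrees(np.arccos(np.clip(cosang, 0, 1))).max() < 2.0

    def test_sphere_normals_outward(self, sphere_mesh):
        e3 = sphere_mesh.frame[:, 2]
        out = sphere_mesh.centroids()
        out /= np.linalg.norm(out, axis=1, keepdims=True)
        assert np.all(np.einsum("ij,ij->i", e3, out) > 0.99)

    def test_frames_orthonormal_determinant_one(self, col0_mesh_coarse):
        f = col0_mesh_coarse.frame
        assert np.allclose(np.einsum("eij,ekj->eik", f, f),
                           np.eye(3), atol=1e-8)
        assert np.allclose(np.linalg.det(f), 1.0, atol=1e-8)


class TestIO:
    def test_landmark_csv_round_trip(self, tmp_path, col0_closed):
        lms = synth.generate_landmarks(col0_closed, seed=2)
        path = tmp_path / "lm.csv"
        export_landmarks(lms, path)
        back = import_landmarks(path)
        for cid in lms.rings:
            assert len(back.rings[cid]) == len(lms.rings[cid])
            for a, b in zip(back.rings[cid], lms.rings[cid]):
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_out_of_order_rings_rejected(self, tmp_path):
        import pandas as pd

        rows = []
        for ri in (1, 0):  # wrong order
            for pi in range(6):
                rows.append((1, ri, pi, pi * 1.0, ri * 1.0, 0.0))
        df = pd.DataFrame(rows, columns=["cell_id", "ring_index",
                                         "point_index", "x", "y", "z"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row"):
            import_landmarks(path)

    def test_mesh_vtk_round_trip(self, tmp_path, col0_mesh_coarse):
        path = tmp_path / "m.vtk"
        export_mesh(col0_mesh_coarse, path)
        back = import_mesh(path)
        assert len(back.nodes) == len(col0_mesh_coarse.nodes)
        assert len(back.triangles) == len(col0_mesh_coarse.triangles)
        np.testing.assert_allclose(back.nodes, col0_mesh_coarse.nodes,
                                   atol=1e-6)


class TestLandmarkPipeline:
    def test_landmarks_to_welded_mesh(self, col0_closed):
        lms = synth.generate_landmarks(col0_closed, n_rings_per_cell=10,
                                       n_points_per_ring=10)
        mesh = landmarks_to_mesh(lms, n_per_ring=16)
        assert "junction" in mesh.node_sets
        assert len(mesh.node_sets["junction"]) > 0
        assert mesh.frame is not None
        assert set(np.unique(mesh.region)) <= set(REGIONS)

    def test_landmark_validation(self):
        with pytest.raises(ValueError, match="≥8 rings|8 rings"):
            LandmarkSet(rings={1: [np.zeros((6, 3))] * 3})
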