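"""Mesh construction, discrete geometry and local refinement."""

import numpy as np
import pytest

from phagozip import build_sphere_mesh, build_flat_patch, refine_near_frozen
from phagozip.mesh import (
    TriMesh, MeshError, VertexBudgetError, save_off, load_off, save_ply,
    load_ply,
)
from phagozip.geometry import (
    enclosed_volume, square_curvature, vertex_areas, mesh_geometry,
    gaussian_curvature_integral,
)
from phagozip.particles import Sphere


class TestSphereMesh:
    def test_area_and_volume_converge(self, unit_icosphere):
        g = mesh_geometry(unit_icosphere)
        assert g.total_area == pytest.approx(4 * np.pi, rel=5e-3)
        assert g.volume == pytest.approx(4 * np.pi / 3, rel=5e-3)

    def test_outward_orientation(self, unit_icosphere):
        assert enclosed_volume(unit_icosphere) > 0

    def test_inverted_orientation_flips_sign(self, coarse_icosphere):
        flipped = TriMesh(coarse_icosphere.vertices.copy(),
                          coarse_icosphere.triangles[:, ::-1].copy())
        assert enclosed_volume(flipped) == pytest.approx(
            -enclosed_volume(coarse_icosphere))

    def test_volume_translation_invariant(self, coarse_icosphere):
        shifted = TriMesh(coarse_icosphere.vertices + np.array([3.0, -2, 7]),
                          coarse_icosphere.triangles.copy())
        assert enclosed_volume(shifted) == pytest.approx(
            enclosed_volume(coarse_icosphere), rel=1e-12)

    def test_max_edge_below_target(self, unit_icosphere):
        e = unit_icosphere.edges
        L = np.linalg.norm(unit_icosphere.vertices[e[:, 0]]
                           - unit_icosphere.vertices[e[:, 1]], axis=1)
        assert L.max() <= 0.12 + 1e-12

    @pytest.mark.parametrize("radius,edge", [(-1, 0.1), (1, 0), (1, 2)])
    def test_invalid_inputs(self, radius, edge):
        with pytest.raises(ValueError):
            build_sphere_mesh(radius, edge)


class TestCurvature:
    def test_unit_sphere_square_curvature_is_two(self, unit_icosphere):
        c2 = square_curvature(unit_icosphere)
        assert np.allclose(c2, 2.0, atol=0.02)

    def test_flat_patch_interior_curvature_zero(self):
        patch = build_flat_patch(4.0, 0.4)
        c2 = square_curvature(patch)
        interior = ~patch.boundary_vertices
        assert np.abs(c2[interior]).max() < 1e-10

    def test_cylinder_square_curvature(self):
        # open cylinder of radius rho: C1 = 1/rho, C2 = 0 on the interior
        rho, height = 0.8, 3.0
        n_c, n_z = 48, 24
        th = np.arange(n_c) * 2 * np.pi / n_c
        zs = np.linspace(0, height, n_z)
        verts = np.array([[rho * np.cos(t), rho * np.sin(t), z]
                          for z in zs for t in th])
        tris = []
        for i in range(n_z - 1):
            for j in range(n_c):
                a = i * n_c + j
                b = i * n_c + (j + 1) % n_c
                c = a + n_c
                d = b + n_c
                tris.append((a, b, d))
                tris.append((a, d, c))
        mesh = TriMesh(verts, np.array(tris))
        c2 = square_curvature(mesh)
        interior = ~mesh.boundary_vertices
        assert np.allclose(c2[interior], 1.0 / rho ** 2, rtol=0.01)

    def test_gauss_bonnet_closed_genus0(self, coarse_icosphere):
        assert gaussian_curvature_integral(coarse_icosphere) \
            == pytest.approx(4 * np.pi, abs=1e-9)

    def test_bending_integral_converges_to_8pi(self):
        # discrete integral of C^2 over a sphere -> 8*pi under refinement
        mesh = build_sphere_mesh(1.0, 0.07)
        g = mesh_geometry(mesh)
        integral = (g.square_curvature * g.area_weights).sum()
        assert integral == pytest.approx(8 * np.pi, rel=0.02)

    def test_rigid_motion_invariance(self, coarse_icosphere):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = TriMesh(coarse_icosphere.vertices @ R.T + np.array([1, 2, 3]),
                        coarse_icosphere.triangles.copy())
        assert np.allclose(square_curvature(moved),
                           square_curvature(coarse_icosphere), atol=1e-8)
        assert vertex_areas(moved).sum() == pytest.approx(
            vertex_areas(coarse_icosphere).sum(), rel=1e-12)

    def test_area_weights_positive_and_sum(self, unit_icosphere):
        A = vertex_areas(unit_icosphere)
        g = mesh_geometry(unit_icosphere)
        assert np.all(A > 0)
        assert A.sum() == pytest.approx(g.total_area, rel=1e-12)


class TestRefinement:
    def test_no_centers_returns_same_mesh(self, coarse_icosphere):
        out = refine_near_frozen(coarse_icosphere, np.array([], dtype=int),
                                 0.5, 0.1)
        assert out is coarse_icosphere

    def test_local_edges_below_target(self):
        mesh = build_sphere_mesh(2.0, 0.6)
        center = np.array([int(np.argmax(mesh.vertices[:, 2]))])
        out = refine_near_frozen(mesh, center, 1.0, 0.15)
        e = out.edges
        L = np.linalg.norm(out.vertices[e[:, 0]] - out.vertices[e[:, 1]],
                           axis=1)
        cpos = mesh.vertices[center[0]]
        da = np.linalg.norm(out.vertices[e[:, 0]] - cpos, axis=1)
        db = np.linalg.norm(out.vertices[e[:, 1]] - cpos, axis=1)
        inzone = (da <= 1.0) & (db <= 1.0)
        assert L[inzone].max() <= 0.15 + 1e-12
        assert out.is_closed()

    def test_idempotent_once_resolved(self):
        mesh = build_sphere_mesh(2.0, 0.6)
        center = np.array([0])
        once = refine_near_frozen(mesh, center, 1.0, 0.2)
        twice = refine_near_frozen(once, center, 1.0, 0.2)
        assert twice.n_vertices == once.n_vertices

    def test_positions_and_flags_preserved(self):
        mesh = build_sphere_mesh(2.0, 0.6)
        mesh.frozen[:5] = True
        center = np.array([0])
        out = refine_near_frozen(mesh, center, 1.0, 0.2)
        n0 = mesh.n_vertices
        assert np.array_equal(out.vertices[:n0], mesh.vertices)
        assert np.array_equal(out.frozen[:n0], mesh.frozen)

    def test_vertex_budget_error(self):
        mesh = build_sphere_mesh(2.0, 0.6)
        with pytest.raises(VertexBudgetError):
            refine_near_frozen(mesh, np.array([0]), 2.0, 0.02,
                               max_vertices=mesh.n_vertices + 10)

    def test_midpoints_pushed_out_of_particle(self):
        mesh = build_sphere_mesh(2.0, 0.6)
        shape = Sphere(radius=1.0)
        shape.place_above(2.0)
        center = np.array([int(np.argmax(mesh.vertices[:, 2]))])
        out = refine_near_frozen(mesh, center, 1.0, 0.1, shape=shape,
                                 shell_offset=0.02)
        assert shape.signed_distance(out.vertices).min() >= -1e-9


class TestIO:
    def test_off_roundtrip(self, tmp_path, coarse_icosphere):
        p = tmp_path / "m.off"
        save_off(coarse_icosphere, p)
        back = load_off(p)
        assert np.allclose(back.vertices, coarse_icosphere.vertices,
                           atol=1e-6)
        assert np.array_equal(back.triangles, coarse_icosphere.triangles)

    def test_ply_roundtrip_with_frozen(self, tmp_path, coarse_icosphere):
        mesh = coarse_icosphere.copy()
        mesh.frozen[::3] = True
        p = tmp_path / "m.ply"
        save_ply(mesh, p)
        back = load_ply(p)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert np.array_equal(back.frozen, mesh.frozen)

    def test_bad_triangle_rejected(self):
        with pytest.raises(MeshError):
            TriMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
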