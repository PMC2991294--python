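"""Discrete differential geometry on triangle meshes.

The bending energy uses the square curvature C^2 = C1^2 + C2^2 (sum of the
squared principal curvatures).  With mean curvature H = (C1 + C2)/2 and
Gaussian curvature K = C1*C2 this is (2H)^2 - 2K.  We compute 2H from the
cotangent Laplace-Beltrami operator applied to the vertex positions (with
Meyer mixed Voronoi area weights) and K from the angle defect; both are
standard, convergent discretisations whose closed forms on spheres,
cylinders and flat patches serve as tests.  The Gaussian term C1*C2 summed
over a closed surface is a topological constant (Gauss-Bonnet) and is
excluded from the energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh, MeshError


class DegenerateTriangleError(MeshError):
    """A triangle with (near-)zero area was encountered."""


def triangle_areas_normals(positions: np.ndarray, tris: np.ndarray):
    p0 = positions[tris[:, 0]]
    p1 = positions[tris[:, 1]]
    p2 = positions[tris[:, 2]]
    cr = np.cross(p1 - p0, p2 - p0)
    a2 = np.linalg.norm(cr, axis=1)
    areas = 0.5 * a2
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cr / np.where(a2 > 0, a2, 1.0)[:, None]
    return areas, normals


def triangle_signed_volumes(positions: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Per-triangle contribution det(p0, p1, p2)/6 to the enclosed volume."""
    p0 = positions[tris[:, 0]]
    p1 = positions[tris[:, 1]]
    p2 = positions[tris[:, 2]]
    return np.einsum("ij,ij->i", p0, np.cross(p1, p2)) / 6.0


def enclosed_volume(mesh: TriMesh, positions: np.ndarray | None = None) -> float:
    """Signed enclosed volume via the divergence theorem.

    Positive for a closed, outward-oriented surface.  Raises for open
    meshes, for which the quantity is not well defined.
    """
    if not mesh.is_closed():
        raise MeshError("enclosed volume requires a closed mesh")
    pos = mesh.vertices if positions is None else positions
    return float(triangle_signed_volumes(pos, mesh.triangles).sum())


def _corner_fields(positions, tris, min_area):
    """Per-corner cotangents, angles and Meyer mixed areas.

    Returns (cot, ang, amix, areas) each with shape (m, 3), corner order
    matching the triangle's vertex order.
    """
    p = positions[tris]  # (m, 3, 3)
    # edge opposite corner c: from the next vertex to the one after
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    l2 = np.stack(
        [np.einsum("ij,ij->i", e0, e0),
         np.einsum("ij,ij->i", e1, e1),
         np.einsum("ij,ij->i", e2, e2)], axis=1
    )
    cr = np.cross(e2, -e1)
    area2 = np.linalg.norm(cr, axis=1)  # 2 * area
    areas = 0.5 * area2
    if np.any(areas < min_area):
        raise DegenerateTriangleError("zero-area triangle")
    # cot at corner i = (l_j^2 + l_k^2 - l_i^2) / (4 * area)
    cot = np.empty_like(l2)
    cot[:, 0] = (l2[:, 1] + l2[:, 2] - l2[:, 0])
    cot[:, 1] = (l2[:, 2] + l2[:, 0] - l2[:, 1])
    cot[:, 2] = (l2[:, 0] + l2[:, 1] - l2[:, 2])
    cot /= (2.0 * area2)[:, None]
    ang = np.arctan2(area2[:, None], cot * area2[:, None])  # = atan(1/cot)
    # Meyer mixed area: Voronoi for non-obtuse triangles, else T/2 at the
    # obtuse corner and T/4 at the other two.
    amix = (l2[:, [1, 2, 0]] * cot[:, [1, 2, 0]] +
            l2[:, [2, 0, 1]] * cot[:, [2, 0, 1]]) / 8.0
    obtuse = cot < 0.0  # corner angle > pi/2
    any_obtuse = obtuse.any(axis=1)
    if np.any(any_obtuse):
        rows = np.where(any_obtuse)[0]
        amix[rows] = (areas[rows] / 4.0)[:, None]
        oc = np.argmax(obtuse[rows], axis=1)
        amix[rows, oc] = areas[rows] / 2.0
    return cot, ang, amix, areas


def vertex_fields(
    positions: np.ndarray,
    tris: np.ndarray,
    vertex_ids: np.ndarray,
    boundary_mask: np.ndarray | None = None,
    min_area: float = 1e-12,
    compact_map=None,
):
    """Mixed areas, (2H)^2 and angle-defect K for ``vertex_ids``.

    ``tris`` must contain the complete incident fan of every requested
    vertex (extra triangles are harmless).  Returns (A, H2, K) arrays
    aligned with ``vertex_ids``.  ``compact_map`` may supply precomputed
    (all_vs, inv, sel): the sorted vertex ids appearing in ``tris``, the
    per-corner compact indices, and the compact positions of
    ``vertex_ids`` (a caller-side cache for the Monte Carlo hot path).
    """
    vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
    cot, ang, amix, _ = _corner_fields(positions, tris, min_area)
    m = len(tris)
    if compact_map is None:
        all_vs, inv = np.unique(tris.ravel(), return_inverse=True)
        inv = inv.reshape(m, 3)
        sel = np.searchsorted(all_vs, vertex_ids)
        if np.any(all_vs[sel] != vertex_ids):
            raise MeshError("vertex_ids not covered by supplied triangles")
    else:
        all_vs, inv, sel = compact_map
    nn = len(all_vs)
    flat = inv.ravel()
    A = np.bincount(flat, weights=amix.ravel(), minlength=nn)
    angsum = np.bincount(flat, weights=ang.ravel(), minlength=nn)
    # cotan Laplacian: corner i of (i, j, k) receives
    # cot(k)*(x_i - x_j) + cot(j)*(x_i - x_k)
    p = positions[tris]
    d1 = p - p[:, [1, 2, 0]]   # x_c - x_{c+1}
    d2 = p - p[:, [2, 0, 1]]   # x_c - x_{c+2}
    contrib = (cot[:, [2, 0, 1], None] * d1
               + cot[:, [1, 2, 0], None] * d2).reshape(-1, 3)
    lap = np.column_stack([
        np.bincount(flat, weights=contrib[:, 0], minlength=nn),
        np.bincount(flat, weights=contrib[:, 1], minlength=nn),
        np.bincount(flat, weights=contrib[:, 2], minlength=nn)])
    Asel = A[sel]
    if np.any(Asel <= 0):
        raise DegenerateTriangleError("vertex with non-positive mixed area")
    mean_vec = lap[sel] / (2.0 * Asel[:, None])  # magnitude 2|H|
    H2 = np.einsum("ij,ij->i", mean_vec, mean_vec)
    full = 2.0 * np.pi
    if boundary_mask is not None:
        defect = np.where(boundary_mask[vertex_ids], np.pi, full) - angsum[sel]
    else:
        defect = full - angsum[sel]
    K = defect / Asel
    return Asel, H2, K


def square_curvature(mesh: TriMesh, positions: np.ndarray | None = None) -> np.ndarray:
    """Per-vertex square curvature C^2 = C1^2 + C2^2 = (2H)^2 - 2K."""
    pos = mesh.vertices if positions is None else positions
    ids = np.arange(mesh.n_vertices)
    A, H2, K = vertex_fields(pos, mesh.triangles, ids,
                             boundary_mask=mesh.boundary_vertices)
    return H2 - 2.0 * K


def vertex_areas(mesh: TriMesh, positions: np.ndarray | None = None) -> np.ndarray:
    """Meyer mixed Voronoi area weight per vertex; sums to the total area."""
    pos = mesh.vertices if positions is None else positions
    _, _, amix, _ = _corner_fields(pos, mesh.triangles, 1e-12)
    A = np.zeros(mesh.n_vertices)
    np.add.at(A, mesh.triangles.ravel(), amix.ravel())
    return A


def gaussian_curvature_integral(mesh: TriMesh) -> float:
    """Sum of angle defects; 4*pi for any closed genus-0 mesh (Gauss-Bonnet)."""
    _, ang, _, _ = _corner_fields(mesh.vertices, mesh.triangles, 1e-12)
    angsum = np.zeros(mesh.n_vertices)
    np.add.at(angsum, mesh.triangles.ravel(), ang.ravel())
    full = np.where(mesh.boundary_vertices, np.pi, 2.0 * np.pi)
    return float((full - angsum).sum())


@dataclass
class MeshGeometry:
    """Discrete geometric fields of a membrane mesh."""

    square_curvature: np.ndarray  # per-vertex C1^2 + C2^2, um^-2
    area_weights: np.ndarray      # per-vertex mixed area, um^2
    total_area: float             # um^2
    volume: float                 # enclosed volume, um^3 (closed meshes)


def mesh_geometry(mesh: TriMesh) -> MeshGeometry:
    pos = mesh.vertices
    ids = np.arange(mesh.n_vertices)
    A, H2, K = vertex_fields(pos, mesh.triangles, ids,
                             boundary_mask=mesh.boundary_vertices)
    vol = enclosed_volume(mesh) if mesh.is_closed() else float("nan")
    return MeshGeometry(H2 - 2.0 * K, A, float(A.sum()), vol)
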