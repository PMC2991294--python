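"""Triangulated membrane surface with local refinement.

The cell membrane is a closed, outward-oriented triangle mesh.  Vertices
carry a ``frozen`` flag: in the active zipper, vertices that come within the
ligand-receptor contact shell of the particle are immobilised for the rest
of the simulation, and the mesh is refined locally around them so the
advancing cup stays resolved at the contact mesh size R0 while the rest of
the cell remains coarse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh


class MeshError(Exception):
    """Raised for invalid or degenerate mesh operations."""


class VertexBudgetError(MeshError):
    """Refinement would exceed the configured vertex budget.

    Signals a resolution/feasibility limit rather than a programming error.
    """


def gather_csr(indptr: np.ndarray, indices: np.ndarray,
               rows: np.ndarray) -> np.ndarray:
    """Concatenate CSR rows (vectorised, possibly with duplicates)."""
    rows = np.asarray(rows, dtype=np.int64)
    counts = indptr[rows + 1] - indptr[rows]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=indices.dtype)
    rep = np.repeat(np.arange(len(rows)), counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    return indices[indptr[rows][rep] + within]


def _build_csr(items_per_row: list[np.ndarray], n_rows: int):
    counts = np.array([len(r) for r in items_per_row], dtype=np.int64)
    indptr = np.zeros(n_rows + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    if len(items_per_row):
        indices = np.concatenate(items_per_row)
    else:
        indices = np.empty(0, dtype=np.int64)
    return indptr, indices.astype(np.int64)


@dataclass
class TriMesh:
    """Triangle mesh with per-vertex mobility flags.

    Parameters
    ----------
    vertices : (n, 3) float array, positions in um.
    triangles : (m, 3) int array, consistently oriented vertex triples
        (outward normals for a closed cell).
    frozen : (n,) bool array, immobilised vertices (active zipper).
    boundary_tag : (n,) bool array, pinned frame vertices for open patches
        (unused for the closed cell).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    frozen: np.ndarray = None
    boundary_tag: np.ndarray = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        n = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (m, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise MeshError("triangle references a non-existent vertex")
        if any(
            len(set(t)) != 3 for t in self.triangles[: min(len(self.triangles), 0)]
        ):  # full check in validate()
            raise MeshError("degenerate triangle")
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool).copy()
        if self.boundary_tag is None:
            self.boundary_tag = np.zeros(n, dtype=bool)
        else:
            self.boundary_tag = np.asarray(self.boundary_tag, dtype=bool).copy()

    # -- basic properties -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.triangles.copy(),
            self.frozen.copy(),
            self.boundary_tag.copy(),
        )

    def invalidate(self):
        """Drop connectivity caches after a structural change."""
        self._cache.clear()

    def validate(self):
        t = self.triangles
        if np.any(t[:, 0] == t[:, 1]) or np.any(t[:, 1] == t[:, 2]) or np.any(
            t[:, 0] == t[:, 2]
        ):
            raise MeshError("triangle with repeated vertex")

    # -- connectivity -----------------------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as sorted (a, b) pairs, shape (E, 2)."""
        if "edges" not in self._cache:
            e = np.vstack(
                [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                 self.triangles[:, [2, 0]]]
            )
            e = np.sort(e, axis=1)
            uniq, counts = np.unique(e, axis=0, return_counts=True)
            self._cache["edges"] = uniq
            self._cache["edge_counts"] = counts
        return self._cache["edges"]

    @property
    def edge_counts(self) -> np.ndarray:
        self.edges
        return self._cache["edge_counts"]

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Bool mask of vertices on a boundary edge (edge with one face)."""
        if "boundary_vertices" not in self._cache:
            mask = np.zeros(self.n_vertices, dtype=bool)
            be = self.edges[self.edge_counts == 1]
            mask[be.ravel()] = True
            self._cache["boundary_vertices"] = mask
        return self._cache["boundary_vertices"]

    def is_closed(self) -> bool:
        return bool(np.all(self.edge_counts == 2))

    @property
    def neighbors_csr(self):
        """(indptr, indices) adjacency over undirected edges."""
        if "neighbors" not in self._cache:
            e = self.edges
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            order = np.argsort(src, kind="stable")
            src, dst = src[order], dst[order]
            indptr = np.searchsorted(src, np.arange(self.n_vertices + 1))
            self._cache["neighbors"] = (indptr.astype(np.int64), dst)
        return self._cache["neighbors"]

    @property
    def vertex_triangles_csr(self):
        """(indptr, tri_indices): triangles incident to each vertex."""
        if "vtris" not in self._cache:
            m = self.n_triangles
            tri_ids = np.repeat(np.arange(m, dtype=np.int64), 3)
            verts = self.triangles.ravel()
            order = np.argsort(verts, kind="stable")
            verts, tri_ids = verts[order], tri_ids[order]
            indptr = np.searchsorted(verts, np.arange(self.n_vertices + 1))
            self._cache["vtris"] = (indptr.astype(np.int64), tri_ids)
        return self._cache["vtris"]

    def incident_triangles(self, vertex_ids: np.ndarray) -> np.ndarray:
        """Unique triangle indices incident to any of ``vertex_ids``."""
        indptr, tri_ids = self.vertex_triangles_csr
        return np.unique(gather_csr(indptr, tri_ids, np.atleast_1d(vertex_ids)))

    def ring(self, vertex_ids: np.ndarray) -> np.ndarray:
        """Unique vertex ids of ``vertex_ids`` plus their 1-ring."""
        indptr, nbrs = self.neighbors_csr
        vertex_ids = np.atleast_1d(np.asarray(vertex_ids, dtype=np.int64))
        nb = gather_csr(indptr, nbrs, vertex_ids)
        return np.unique(np.concatenate([vertex_ids, nb]))

    def geodesic_ball(self, center: int, radius: float) -> np.ndarray:
        """Vertices within Euclidean distance ``radius`` of ``center``,
        restricted to the edge-connected neighborhood (breadth-first)."""
        indptr, nbrs = self.neighbors_csr
        pos = self.vertices
        c = pos[center]
        visited = np.zeros(self.n_vertices, dtype=bool)
        visited[center] = True
        frontier = np.array([center], dtype=np.int64)
        r2 = radius * radius
        while len(frontier):
            nxt = gather_csr(indptr, nbrs, frontier)
            nxt = nxt[~visited[nxt]]
            if not len(nxt):
                break
            diff = pos[nxt] - c
            nxt = nxt[np.einsum("ij,ij->i", diff, diff) <= r2]
            keep = np.unique(nxt)
            visited[keep] = True
            frontier = keep
        return np.flatnonzero(visited)


# -- constructors ---------------------------------------------------------


def build_sphere_mesh(radius: float, target_edge: float) -> TriMesh:
    """Closed, outward-oriented icosphere with max edge <= target_edge.

    Subdivision level is the smallest for which the icosahedral edge length
    (~1.0515 * radius at level 0, halved per level) drops below the target.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 < target_edge < radius):
        raise ValueError("target_edge must be in (0, radius)")
    base_edge = 1.0515 * radius
    level = max(0, int(np.ceil(np.log2(base_edge / target_edge))))
    tm = _trimesh.creation.icosphere(subdivisions=level, radius=radius)
    mesh = TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    from .geometry import enclosed_volume

    if enclosed_volume(mesh) < 0:  # ensure outward orientation
        mesh.triangles = mesh.triangles[:, ::-1].copy()
        mesh.invalidate()
    return mesh


def build_flat_patch(side: float, target_edge: float, z: float = 0.0) -> TriMesh:
    """Square membrane patch in the z-plane with a pinned (frozen) frame.

    Used for equilibrium fluctuation-spectrum checks; the boundary frame is
    both ``frozen`` and ``boundary_tag``-ged so Monte Carlo moves never
    displace it.
    """
    if side <= 0 or target_edge <= 0:
        raise ValueError("side and target_edge must be positive")
    n = max(2, int(np.ceil(side / target_edge)) + 1)
    xs = np.linspace(-side / 2, side / 2, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(n * n, float(z))])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            if (i + j) % 2 == 0:
                tris.append((a, b, d))
                tris.append((a, d, c))
            else:
                tris.append((a, b, c))
                tris.append((b, d, c))
    mesh = TriMesh(verts, np.array(tris, dtype=np.int64))
    edge = mesh.boundary_vertices.copy()
    mesh.frozen = edge.copy()
    mesh.boundary_tag = edge
    return mesh


# -- local refinement -----------------------------------------------------


def refine_near_frozen(
    mesh: TriMesh,
    centers: np.ndarray,
    range_: float,
    target_edge: float,
    shape=None,
    shell_offset: float = 0.0,
    max_vertices: int = 200_000,
    parents_out: list | None = None,
    vertex_scale: np.ndarray | None = None,
    curvature_frac: float | None = None,
) -> TriMesh:
    """Bisect edges near immobilised/contact vertices until <= target_edge.

    Edges with both endpoints within ``range_`` of any center vertex are
    bisected until no longer than ``target_edge``, using terminal
    longest-edge (Rivara-style) bisection: each pass splits edges that are
    the longest edge of every triangle containing them, which keeps the
    mesh conforming and triangle quality bounded.  Existing vertex
    positions and frozen flags are preserved; midpoints inherit frozen
    status only from two frozen parents, and midpoints falling inside the
    particle ``shape`` are pushed out along the signed-distance gradient to
    ``shell_offset``.  Raises :class:`VertexBudgetError` if refinement
    would exceed ``max_vertices``.
    """
    if range_ <= 0:
        raise ValueError("range must be positive")
    centers = np.atleast_1d(np.asarray(centers, dtype=np.int64))
    if centers.size == 0:
        return mesh
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.vertices[centers])
    verts = mesh.vertices
    tris = mesh.triangles
    frozen = mesh.frozen
    boundary = mesh.boundary_tag
    scl = None if vertex_scale is None else np.asarray(vertex_scale,
                                                      dtype=np.float64)
    changed = False
    while True:
        m = len(tris)
        # edge table; edge j of a triangle is opposite corner j
        pairs = np.concatenate([tris[:, [1, 2]], tris[:, [2, 0]],
                                tris[:, [0, 1]]])
        pairs = np.sort(pairs, axis=1)
        edges, inv = np.unique(pairs, axis=0, return_inverse=True)
        tri_edge = inv.reshape(3, m).T  # (m, 3), column j opposite corner j
        ne = len(edges)
        L = np.linalg.norm(verts[edges[:, 0]] - verts[edges[:, 1]], axis=1)
        dcen = tree.query(verts, k=1)[0]
        inzone = (dcen[edges[:, 0]] <= range_) & (dcen[edges[:, 1]] <= range_)
        if curvature_frac is not None and shape is not None:
            # resolve high-curvature particle regions finer: the local
            # target is curvature_frac times the smallest principal
            # curvature radius of the nearby particle surface
            target_e = np.full(ne, target_edge)
            cand_mask = inzone & (L > 0.4 * target_edge)
            if np.any(cand_mask):
                mids_q = 0.5 * (verts[edges[cand_mask, 0]]
                                + verts[edges[cand_mask, 1]])
                near = np.abs(shape.signed_distance(mids_q)) < 1.5 * range_
                if np.any(near):
                    sub = np.flatnonzero(cand_mask)[near]
                    rad = shape.local_curvature_radius(
                        0.5 * (verts[edges[sub, 0]] + verts[edges[sub, 1]]))
                    target_e[sub] = np.minimum(
                        target_edge, np.maximum(curvature_frac * rad,
                                                0.3 * target_edge))
            wanted = (L > target_e) & inzone
        else:
            wanted = (L > target_edge) & inzone
        if scl is not None:
            # only split under-resolved (coarse-born) edges; edges between
            # fine-born vertices that merely stretched are left alone (the
            # tether bounds how far they can go)
            coarse_born = (np.maximum(scl[edges[:, 0]], scl[edges[:, 1]])
                           > target_edge)
            wanted &= coarse_born
        if not np.any(wanted):
            break
        # longest edge per triangle (deterministic tie-break by edge index)
        key = L[tri_edge] * (1.0 + 1e-12 * tri_edge)
        longest = tri_edge[np.arange(m), np.argmax(key, axis=1)]
        # closure: triangles with a wanted edge, plus triangles containing
        # a candidate longest edge of another closure triangle
        need_tri = wanted[tri_edge].any(axis=1)
        for _ in range(64):
            cand = np.zeros(ne, dtype=bool)
            cand[longest[need_tri]] = True
            grow = cand[tri_edge].any(axis=1)
            if not np.any(grow & ~need_tri):
                break
            need_tri |= grow
        cnt_all = np.bincount(tri_edge.ravel(), minlength=ne)
        cnt_longest = np.zeros(ne, dtype=np.int64)
        np.add.at(cnt_longest, longest, 1)
        sel = cand & (cnt_longest == cnt_all)
        sel_ids = np.flatnonzero(sel)
        if not len(sel_ids):
            break  # cannot make progress (should not happen)
        if len(verts) + len(sel_ids) > max_vertices:
            raise VertexBudgetError(
                f"refinement would exceed vertex budget {max_vertices}")
        # midpoints
        ea, eb = edges[sel_ids, 0], edges[sel_ids, 1]
        mids = 0.5 * (verts[ea] + verts[eb])
        if shape is not None:
            d = shape.signed_distance(mids)
            inside = d < 0.0
            if np.any(inside):
                g = shape.sdf_gradient(mids[inside])
                mids[inside] += g * (shell_offset - d[inside])[:, None]
        n0 = len(verts)
        mid_of = np.full(ne, -1, dtype=np.int64)
        mid_of[sel_ids] = n0 + np.arange(len(sel_ids))
        if parents_out is not None:
            parents_out.append(np.column_stack([ea, eb]))
        if scl is not None:
            scl = np.concatenate(
                [scl, 0.5 * np.linalg.norm(verts[ea] - verts[eb], axis=1)])
        verts = np.vstack([verts, mids])
        frozen = np.concatenate([frozen, frozen[ea] & frozen[eb]])
        boundary = np.concatenate([boundary, boundary[ea] & boundary[eb]])
        # split triangles: at most one selected edge per triangle
        tri_sel = sel[tri_edge]  # (m, 3)
        has = tri_sel.any(axis=1)
        j = np.argmax(tri_sel, axis=1)  # which corner the split edge opposes
        keep = tris[~has]
        th = tris[has]
        jh = j[has]
        mh = mid_of[tri_edge[has, jh]]
        i0 = th[np.arange(len(th)), jh]
        i1 = th[np.arange(len(th)), (jh + 1) % 3]
        i2 = th[np.arange(len(th)), (jh + 2) % 3]
        child1 = np.column_stack([i0, i1, mh])
        child2 = np.column_stack([i0, mh, i2])
        tris = np.vstack([keep, child1, child2])
        changed = True
    if not changed:
        return mesh
    return TriMesh(verts, tris, frozen, boundary)


# -- ASCII IO -------------------------------------------------------------


def save_off(mesh: TriMesh, path):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def load_off(path) -> TriMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise MeshError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    p = 4
    verts = np.array(tokens[p:p + 3 * nv], dtype=np.float64).reshape(nv, 3)
    p += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[p])
        tris.append([int(x) for x in tokens[p + 1:p + 1 + k]])
        p += k + 1
    return TriMesh(verts, np.array(tris, dtype=np.int64))


def save_ply(mesh: TriMesh, path):
    """ASCII PLY with the frozen flag as a uchar vertex property."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar frozen\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v, f in zip(mesh.vertices, mesh.frozen):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {int(f)}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def load_ply(path) -> TriMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0].strip() != "ply":
        raise MeshError("not a PLY file")
    nv = nf = 0
    vprops = []
    i = 1
    element = None
    while lines[i].strip() != "end_header":
        parts = lines[i].split()
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                nv = int(parts[2])
            elif element == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and element == "vertex":
            vprops.append(parts[-1])
        i += 1
    i += 1
    verts = np.zeros((nv, 3))
    frozen = np.zeros(nv, dtype=bool)
    has_frozen = "frozen" in vprops
    fz_idx = vprops.index("frozen") if has_frozen else -1
    for k in range(nv):
        vals = lines[i + k].split()
        verts[k] = [float(vals[vprops.index(ax)]) for ax in ("x", "y", "z")]
        if has_frozen:
            frozen[k] = bool(int(float(vals[fz_idx])))
    i += nv
    tris = []
    for k in range(nf):
        vals = lines[i + k].split()
        cnt = int(vals[0])
        tris.append([int(x) for x in vals[1:1 + cnt]])
    return TriMesh(verts, np.array(tris, dtype=np.int64), frozen)
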