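"""Engulfment and phagocytic-cup shape statistics.

These metrics are shared between simulation meshes and (via the imaging
module) confocal-like image stacks:

* engulfed fraction - percentage of the particle's surface area lying
  within the contact-shell distance R0 of the membrane;
* 24-segment height profile - for each of 24 equal angular sectors around
  the particle's vertical axis, the maximum height at which membrane is
  present in the particle's immediate neighborhood, measured from the
  particle's bottom contact plane;
* cup variability - dispersion of the height profile, by default the
  standard deviation divided by the square root of the mean height, which
  removes the trivial growth of the spread with cup size;
* regular/variable classification against a reference mean variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriMesh

N_SEGMENTS = 24


# -- exact point-to-surface distance --------------------------------------


def _point_triangle_distance(p, a, b, c):
    """Vectorised exact distance from points p to triangles (a, b, c).

    All arguments (k, 3); returns (k,).  Standard closest-point-on-triangle
    region test.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    closest[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    t = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    t = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom != 0, denom, 1.0), 0.0)
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1)


def point_mesh_distance(points: np.ndarray, mesh: TriMesh,
                        k_candidates: int = 8) -> np.ndarray:
    """Distance from each point to the mesh surface.

    Exact point-triangle distance over the ``k_candidates`` triangles with
    nearest centroids (adequate when triangles are small compared to the
    query scale).
    """
    tris = mesh.triangles
    pos = mesh.vertices
    centroids = pos[tris].mean(axis=1)
    k = min(k_candidates, len(tris))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx)
    if idx.ndim == 1:
        idx = idx[:, None]
    n = len(points)
    p_rep = np.repeat(points, k, axis=0)
    t_rep = tris[idx.ravel()]
    d = _point_triangle_distance(p_rep, pos[t_rep[:, 0]], pos[t_rep[:, 1]],
                                 pos[t_rep[:, 2]])
    return d.reshape(n, k).min(axis=1)


# -- engulfment -----------------------------------------------------------


def engulfed_fraction_mesh(mesh: TriMesh, shape, R0: float,
                           n_samples: int = 1500) -> float:
    """Percentage of the particle surface area within R0 of the membrane."""
    pts, w = shape.surface_points_weighted(n_samples)
    d = point_mesh_distance(pts, mesh)
    return float(100.0 * w[d <= R0].sum() / w.sum())


# -- height profiles ------------------------------------------------------


@dataclass
class CupProfile:
    """24-segment membrane-height profile around a particle.

    ``heights`` are in um for meshes, or integer z-plane indices times the
    z-step for image stacks.  ``flagged`` marks particles with no detected
    membrane at all.
    """

    heights: np.ndarray
    particle: object = None
    engulfed_pct: float = 0.0
    flagged: bool = False

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.shape != (N_SEGMENTS,):
            raise ValueError(f"profile must have exactly {N_SEGMENTS} segments")
        if np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")


def height_profile(mesh: TriMesh, shape, R0: float,
                   n_segments: int = N_SEGMENTS) -> CupProfile:
    """Membrane height around the particle, per angular segment.

    For each of 24 equal azimuthal sectors about the particle's vertical
    axis, the maximum z of membrane vertices lying within the contact
    neighborhood (sdf < R0), measured from the particle's bottom contact
    plane.
    """
    if n_segments != N_SEGMENTS:
        raise ValueError("the profile is defined on 24 segments")
    # sample the surface, not just the vertex cloud: stretched triangles
    # can dip into the contact neighbourhood between their corners
    e = mesh.edges
    midpoints = 0.5 * (mesh.vertices[e[:, 0]] + mesh.vertices[e[:, 1]])
    centroids = mesh.vertices[mesh.triangles].mean(axis=1)
    cand = np.vstack([mesh.vertices, midpoints, centroids])
    sdf = shape.signed_distance(cand)
    near = sdf < R0
    z_bottom = shape.lowest_point_z()
    heights = np.zeros(n_segments)
    if not np.any(near):
        prof = CupProfile(heights, particle=shape, flagged=True)
        return prof
    pts = cand[near]
    center = shape.translation
    ang = np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0])
    seg = np.floor((ang + np.pi) / (2 * np.pi) * n_segments).astype(int)
    seg = np.clip(seg, 0, n_segments - 1)
    h = np.maximum(pts[:, 2] - z_bottom, 0.0)
    np.maximum.at(heights, seg, h)
    prof = CupProfile(heights, particle=shape)
    prof.engulfed_pct = mean_height_engulfment(prof)
    return prof


def mean_height_engulfment(profile: CupProfile) -> float:
    """Engulfment percentage from the average membrane height:
    100 * mean(heights) / particle vertical extent."""
    if profile.particle is None:
        raise ValueError("profile has no particle reference")
    extent = profile.particle.vertical_extent()
    return float(100.0 * profile.heights.mean() / extent)


# -- variability ----------------------------------------------------------


def cup_variability(profile: CupProfile,
                    definition: str = "std_over_sqrt_mean") -> float:
    """Cup-shape variability statistic of a height profile.

    ``std_over_sqrt_mean`` (default): population standard deviation of the
    24 heights divided by the square root of their mean -- removes the
    trivial scaling of the spread with cup size.  ``std_over_mean`` is the
    dimensionless alternative (coefficient of variation).
    """
    h = profile.heights
    mean = h.mean()
    if mean <= 0:
        raise ValueError("cup variability undefined for zero mean height")
    std = h.std()  # population convention (divide by N)
    if definition == "std_over_sqrt_mean":
        return float(std / np.sqrt(mean))
    if definition == "std_over_mean":
        return float(std / mean)
    raise ValueError(f"unknown variability definition {definition!r}")


def classify_cup(variability: float, reference_mean: float) -> str:
    """'regular' iff strictly below the reference mean variability."""
    return "regular" if variability < reference_mean else "variable"
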