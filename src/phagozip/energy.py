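"""Free energy of the membrane-particle system.

Total energy E = E_m + E_vol + E_LR:

* ``E_m``  - Helfrich membrane energy: integral of kappa_b/2 * C^2 + sigma
  over the membrane, with C^2 = C1^2 + C2^2 the sum of squared principal
  curvatures (the Gaussian cross term is a topological constant and is
  dropped).
* ``E_vol`` - quadratic cytosol-volume constraint kappa_P (V - V0)^2, the
  lowest-order expansion of the cell's volume-regulation energy around its
  preferred volume V0.
* ``E_LR`` - ligand-receptor contact potential: particle surface covered by
  membrane (any membrane vertex within the shell distance R0) gains
  -epsilon per unit covered particle area (epsilon is the areal
  bond-energy density).

All energies are in pN um; distances in um.  The contact potential is
discretised on the particle surface: the surface is tiled into bins of
roughly R0 lateral size and each bin contributes -epsilon times its area
once at least one bound membrane vertex maps to it (nearest bin).  The
ligand budget per unit particle area is thereby finite: stacking extra
membrane into the shell gains nothing, and the fully wrapped energy is
-epsilon times the particle surface area independent of mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import TriMesh
from .geometry import (
    vertex_fields,
    triangle_signed_volumes,
    enclosed_volume,
)

#: Boltzmann constant in pN um / K (1.380649e-23 J/K = 1.380649e-5 pN um/K)
KB = 1.380649e-5

#: conversion: 1 mN/m = 1e3 pN/um
MN_PER_M_TO_PN_PER_UM = 1.0e3


@dataclass(frozen=True)
class EnergyParams:
    """Biophysical parameters of the membrane model.

    Attributes
    ----------
    kappa_b : bending stiffness, pN um.
    sigma : surface tension, pN / um (use :func:`sigma_from_mN_per_m` or
        ``standard_parameters`` to convert from the mN/m convention).
    kappa_P : cell-volume constraint stiffness, pN um^-5.
    V0 : preferred cytosol volume, um^3.
    epsilon : ligand-receptor binding energy density, pN / um.
    R0 : contact-shell width, um (kept well below 0.1 * particle radius).
    temperature : K.
    """

    kappa_b: float = 1.3e-2
    sigma: float = 6.2e-6 * MN_PER_M_TO_PN_PER_UM
    kappa_P: float = 2.56e-5
    V0: float = 0.0
    epsilon: float = 58.5
    R0: float = 0.075
    temperature: float = 310.0

    def __post_init__(self):
        for name in ("kappa_b", "sigma", "kappa_P", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def with_(self, **kw) -> "EnergyParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "kappa_b": self.kappa_b,
            "sigma_mN_per_m": self.sigma / MN_PER_M_TO_PN_PER_UM,
            "kappa_P": self.kappa_P,
            "V0": self.V0,
            "epsilon": self.epsilon,
            "R0": self.R0,
            "temperature": self.temperature,
        }

    @staticmethod
    def from_dict(d: dict) -> "EnergyParams":
        d = dict(d)
        if "sigma_mN_per_m" in d:
            d["sigma"] = d.pop("sigma_mN_per_m") * MN_PER_M_TO_PN_PER_UM
        return EnergyParams(**d)


def standard_parameters(particle_radius: float = 1.5, V0: float = 0.0,
                        temperature: float = 310.0) -> EnergyParams:
    """The standard parameter set: kappa_b = 1.3e-2 pN um,
    sigma = 6.2e-6 mN/m, epsilon = 58.5 pN/um, kappa_P = 2.56e-5 pN um^-5,
    with the contact-shell width R0 = 0.05 * particle radius."""
    return EnergyParams(
        kappa_b=1.3e-2,
        sigma=6.2e-6 * MN_PER_M_TO_PN_PER_UM,
        kappa_P=2.56e-5,
        V0=V0,
        epsilon=58.5,
        R0=0.05 * particle_radius,
        temperature=temperature,
    )


@dataclass
class EnergyBreakdown:
    """Energy components, pN um.  E_total = E_m + E_vol + E_LR exactly."""

    E_m: float
    E_vol: float
    E_LR: float

    @property
    def E_total(self) -> float:
        return self.E_m + self.E_vol + self.E_LR


# -- component energies ---------------------------------------------------


def _vertex_energy_density(A, H2, K, params: EnergyParams):
    """Bending + tension energy per vertex: (kb/2 C^2 + sigma) * A."""
    c2 = H2 - 2.0 * K
    return (0.5 * params.kappa_b * c2 + params.sigma) * A


def membrane_energy(mesh: TriMesh, params: EnergyParams,
                    positions: np.ndarray | None = None) -> float:
    pos = mesh.vertices if positions is None else positions
    ids = np.arange(mesh.n_vertices)
    A, H2, K = vertex_fields(pos, mesh.triangles, ids,
                             boundary_mask=mesh.boundary_vertices)
    return float(_vertex_energy_density(A, H2, K, params).sum())


def volume_energy(V: float, params: EnergyParams) -> float:
    dv = V - params.V0
    return params.kappa_P * dv * dv


class ContactBins:
    """Tiling of the particle surface for ligand-budget accounting.

    Bin centers/areas come from the shape's deterministic area-weighted
    surface point set at a lateral spacing of about the shell width R0.
    """

    def __init__(self, shape, R0: float):
        from scipy.spatial import cKDTree

        a_bin = np.sqrt(3.0) / 2.0 * R0 * R0
        n = max(64, int(np.ceil(shape.surface_area() / a_bin)))
        self.centers, self.areas = shape.surface_points_weighted(n)
        self.tree = cKDTree(self.centers)
        self.n = len(self.centers)

    def assign(self, points: np.ndarray) -> np.ndarray:
        if len(points) == 0:
            return np.empty(0, dtype=np.int64)
        return self.tree.query(points)[1].astype(np.int64)


def contact_energy(mesh: TriMesh, shape, params: EnergyParams,
                   positions: np.ndarray | None = None,
                   bins: ContactBins | None = None) -> float:
    """-epsilon times the particle surface area covered by membrane.

    A bin of the particle-surface tiling counts as covered when at least
    one membrane vertex lies in the contact shell (0 <= sdf < R0) and maps
    to it.
    """
    pos = mesh.vertices if positions is None else positions
    sdf = shape.signed_distance(pos)
    bound = (sdf >= 0.0) & (sdf < params.R0)
    if not np.any(bound):
        return 0.0
    if bins is None:
        bins = ContactBins(shape, params.R0)
    ids = bins.assign(pos[bound])
    occupied = np.zeros(bins.n, dtype=bool)
    occupied[ids] = True
    return float(-params.epsilon * bins.areas[occupied].sum())


def total_energy(mesh: TriMesh, shape, params: EnergyParams) -> EnergyBreakdown:
    """Full energy breakdown of a closed membrane around a particle.

    The cytosol volume entering the volume constraint is the enclosed mesh
    volume: the hard-core constraint keeps the (exterior) particle outside
    the closed cell surface, so no particle volume is ever enclosed.
    """
    e_m = membrane_energy(mesh, params)
    v = enclosed_volume(mesh) if mesh.is_closed() else 0.0
    e_vol = volume_energy(v, params) if mesh.is_closed() else 0.0
    e_lr = contact_energy(mesh, shape, params) if shape is not None else 0.0
    return EnergyBreakdown(e_m, e_vol, e_lr)


# -- local (stencil) evaluation ------------------------------------------


class LocalEnergyEvaluator:
    """Delta-energy evaluation restricted to the affected stencil.

    A displacement of a vertex set S changes per-vertex energies only on
    S and its 1-ring (their incident fans involve moved positions), the
    enclosed volume only through triangles incident to S, and the contact
    indicator only on S.  The evaluator caches connectivity and totals and
    must be rebuilt (``rebuild``) after any structural mesh change.
    """

    def __init__(self, mesh: TriMesh, shape, params: EnergyParams,
                 bin_size: float | None = None):
        self.mesh = mesh
        self.shape = shape
        self.params = params
        self.bin_size = bin_size  # ligand-bin lateral size; default R0
        self.rebuild()

    def rebuild(self):
        mesh, shape, params = self.mesh, self.shape, self.params
        self._closed = mesh.is_closed()
        n = mesh.n_vertices
        ids = np.arange(n)
        A, H2, K = vertex_fields(mesh.vertices, mesh.triangles, ids,
                                 boundary_mask=mesh.boundary_vertices)
        self.vertex_area = A
        self._H2, self._K = H2, K
        if shape is not None:
            if getattr(self, "bins", None) is None:
                self.bins = ContactBins(
                    shape, self.bin_size if self.bin_size else params.R0)
            self.sdf = shape.signed_distance(mesh.vertices)
            bound = (self.sdf >= 0.0) & (self.sdf < params.R0)
            self.bound = bound
            self.vertex_bin = np.full(n, -1, dtype=np.int64)
            if np.any(bound):
                self.vertex_bin[bound] = self.bins.assign(
                    mesh.vertices[bound])
            self.bin_counts = np.bincount(
                self.vertex_bin[bound], minlength=self.bins.n)
            self.E_LR = float(-params.epsilon
                              * self.bins.areas[self.bin_counts > 0].sum())
        else:
            self.bins = None
            self.sdf = None
            self.bound = np.zeros(n, dtype=bool)
            self.vertex_bin = np.full(n, -1, dtype=np.int64)
            self.E_LR = 0.0
        self.E_m = float(_vertex_energy_density(A, H2, K, params).sum())
        self.V = enclosed_volume(mesh) if self._closed else 0.0
        # scratch buffers for the jitted move kernels
        m = mesh.n_triangles
        self._queue = np.zeros(n, dtype=np.int64)
        self._vstamp = np.zeros(n, dtype=np.int64)
        self._tstamp = np.zeros(m, dtype=np.int64)
        self._stamp_val = 0
        self._affected_buf = np.zeros(n, dtype=np.int64)
        self._fields_buf = np.zeros((n, 3))
        self._in_sup = np.zeros(n, dtype=np.bool_)
        self._idx_sup = np.zeros(n, dtype=np.int64)
        self._bnd_mask = mesh.boundary_vertices

    # ------------------------------------------------------------------

    def breakdown(self) -> EnergyBreakdown:
        e_vol = volume_energy(self.V, self.params) if self._closed else 0.0
        return EnergyBreakdown(self.E_m, e_vol, self.E_LR)

    def _stencil(self, support: np.ndarray):
        """Affected vertices (support + 1-ring), their incident triangles,
        and the volume-changing triangles; mask-based dedup (no sorts)."""
        from .mesh import gather_csr

        mesh = self.mesh
        if not hasattr(self, "_vmask") or \
                len(self._vmask) != mesh.n_vertices:
            self._vmask = np.zeros(mesh.n_vertices, dtype=bool)
            self._tmask = np.zeros(mesh.n_triangles, dtype=bool)
            self._compact = np.zeros(mesh.n_vertices, dtype=np.int64)
        nb_indptr, nb_idx = mesh.neighbors_csr
        vt_indptr, vt_idx = mesh.vertex_triangles_csr
        vmask, tmask = self._vmask, self._tmask
        vmask[support] = True
        vmask[gather_csr(nb_indptr, nb_idx, support)] = True
        affected = np.flatnonzero(vmask)
        vmask[affected] = False
        tmask[gather_csr(vt_indptr, vt_idx, affected)] = True
        tris_e = np.flatnonzero(tmask)
        tmask[tris_e] = False
        tmask[gather_csr(vt_indptr, vt_idx, support)] = True
        tris_v = np.flatnonzero(tmask)
        tmask[tris_v] = False
        return affected, tris_e, tris_v

    def _compact_map(self, tri_sub: np.ndarray, vertex_ids: np.ndarray):
        vmask, compact = self._vmask, self._compact
        flat = tri_sub.ravel()
        vmask[flat] = True
        all_vs = np.flatnonzero(vmask)
        vmask[all_vs] = False
        compact[all_vs] = np.arange(len(all_vs))
        return all_vs, compact[tri_sub], compact[vertex_ids]

    def evaluate(self, support: np.ndarray, new_positions: np.ndarray,
                 min_area: float = 1e-6):
        """Delta energy for displacing ``support`` to ``new_positions``.

        Returns (delta_E, commit) where ``commit()`` applies the move and
        updates all caches.  Raises DegenerateTriangleError if the move
        creates a triangle below ``min_area``.
        """
        mesh, params = self.mesh, self.params
        support = np.asarray(support, dtype=np.int64)
        affected, tris_e, tris_v = self._stencil(support)
        pos_new = mesh.vertices.copy()
        pos_new[support] = new_positions

        tri_sub = mesh.triangles[tris_e]
        cmap = self._compact_map(tri_sub, affected)
        A1, H21, K1 = vertex_fields(pos_new, tri_sub, affected,
                                    boundary_mask=mesh.boundary_vertices,
                                    min_area=min_area, compact_map=cmap)
        dens_new = _vertex_energy_density(A1, H21, K1, params)
        dE_m = float(dens_new.sum()
                     - _vertex_energy_density(
                         self.vertex_area[affected],
                         *self._cached_HK(affected), params).sum())
        # contact: bound state and bin assignment change only on support
        if self.shape is not None:
            sdf_sup = self.shape.signed_distance(new_positions)
            bound_sup = (sdf_sup >= 0.0) & (sdf_sup < params.R0)
            bins_sup = np.full(len(support), -1, dtype=np.int64)
            if np.any(bound_sup):
                bins_sup[bound_sup] = self.bins.assign(
                    new_positions[bound_sup])
            old_bins = self.vertex_bin[support]
            rem = old_bins[old_bins >= 0]
            add = bins_sup[bins_sup >= 0]
            if len(rem) or len(add):
                touched = np.unique(np.concatenate([rem, add]))
                cnt_old = self.bin_counts[touched]
                cnt_new = (cnt_old
                           - np.bincount(np.searchsorted(touched, rem),
                                         minlength=len(touched))
                           + np.bincount(np.searchsorted(touched, add),
                                         minlength=len(touched)))
                dE_lr = float(-params.epsilon * (
                    self.bins.areas[touched]
                    * ((cnt_new > 0).astype(float)
                       - (cnt_old > 0).astype(float))).sum())
            else:
                touched = None
                cnt_new = None
                dE_lr = 0.0
        else:
            sdf_sup = None
            dE_lr = 0.0
        if self._closed:
            tv = mesh.triangles[tris_v]
            dV = float(triangle_signed_volumes(pos_new, tv).sum()
                       - triangle_signed_volumes(mesh.vertices, tv).sum())
            dE_vol = (volume_energy(self.V + dV, params)
                      - volume_energy(self.V, params))
        else:
            dV = 0.0
            dE_vol = 0.0
        dE = dE_m + dE_vol + dE_lr

        def commit():
            mesh.vertices[support] = new_positions
            self.vertex_area[affected] = A1
            self._H2[affected] = H21
            self._K[affected] = K1
            self.E_m += dE_m
            self.E_LR += dE_lr
            self.V += dV
            if self.shape is not None:
                self.sdf[support] = sdf_sup
                self.bound[support] = bound_sup
                self.vertex_bin[support] = bins_sup
                if touched is not None:
                    self.bin_counts[touched] = cnt_new

        return dE, commit

    def _cached_HK(self, ids):
        return self._H2[ids], self._K[ids]


def delta_energy(mesh: TriMesh, shape, params: EnergyParams,
                 support: np.ndarray, displacements: np.ndarray) -> float:
    """Energy change for displacing ``support`` by ``displacements``.

    Evaluated only on the affected stencil; agrees with a global
    before/after recomputation to floating-point accuracy.
    """
    ev = LocalEnergyEvaluator(mesh.copy(), shape, params)
    support = np.asarray(support, dtype=np.int64)
    new_pos = mesh.vertices[support] + np.atleast_2d(displacements)
    dE, _ = ev.evaluate(support, new_pos)
    return dE
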