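"""Rigid particle geometries: spheres, prolate spheroids, spiral rods.

Each shape provides a metric signed distance (negative inside, zero on the
surface, positive outside), its surface area and volume, and approximately
area-uniform surface sampling.  The signed distance defines the
ligand-receptor contact shell (membrane patches with 0 <= sdf < R0 are
bound) and the hard-core constraint (no membrane vertex may have sdf < 0);
the particle itself is rigid and immobile.

Poses are a rotation plus translation applied to the local shape.  The
convention is right-handed coordinates with z up and the cell below the
particle: "tip-first" places a spheroid's major axis along z (normal to the
cell surface at contact), "side-on" places it along x (tangent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _rotation_x_to_z():
    # maps +z to +x (major axis tipped over)
    return np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])


@dataclass
class ParticleShape:
    """Base class; subclasses implement local-frame geometry."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3),
                                 kw_only=True)
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3),
                                    kw_only=True)

    kind = "abstract"

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)

    # -- frame transforms -------------------------------------------------

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.translation) @ self.rotation

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    # -- geometry contracts ----------------------------------------------

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        d = self._sdf_local(self.to_local(pts))
        return float(d[0]) if single else d

    def sdf_gradient(self, points: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """Unit-magnitude gradient of the signed distance (central diff)."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        g = np.zeros_like(pts)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            g[:, ax] = (self.signed_distance(pts + dp)
                        - self.signed_distance(pts - dp)) / (2 * h)
        norm = np.linalg.norm(g, axis=1, keepdims=True)
        return g / np.where(norm > 0, norm, 1.0)

    def surface_area(self) -> float:
        raise NotImplementedError

    def local_curvature_radius(self, points: np.ndarray) -> np.ndarray:
        """Smallest principal curvature radius of the surface near each
        query point; used to set the local mesh resolution needed to wrap
        the shape.  Default: a constant (sphere-like) scale."""
        pts = np.atleast_2d(points)
        r = (3.0 * self.volume() / (4.0 * np.pi)) ** (1.0 / 3.0)
        return np.full(len(pts), r)

    def volume(self) -> float:
        raise NotImplementedError

    def surface_points_weighted(self, n: int):
        """Deterministic surface points with area weights (world frame).

        Returns (points (k, 3), weights (k,)); weights sum to the surface
        area.  Used for engulfed-fraction measurements.
        """
        raise NotImplementedError

    def sample_surface(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Area-uniform random surface samples (world frame)."""
        raise NotImplementedError

    def lowest_point_z(self) -> float:
        """Min z over the surface in the world frame."""
        pts, _ = self.surface_points_weighted(4000)
        return float(pts[:, 2].min())

    def place_above(self, z_top: float, gap: float = 0.0):
        """Translate vertically so the lowest surface point sits at
        ``z_top + gap`` (tangent to a cell whose top pole is at z_top)."""
        dz = z_top + gap - self.lowest_point_z()
        self.translation = self.translation + np.array([0.0, 0.0, dz])
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"kind": self.kind,
             "rotation": self.rotation.tolist(),
             "translation": self.translation.tolist()}
        d.update(self._params_dict())
        return d

    @staticmethod
    def from_dict(d: dict) -> "ParticleShape":
        kind = d["kind"]
        kw = {k: v for k, v in d.items() if k not in ("kind",)}
        kw["rotation"] = np.asarray(kw.get("rotation", np.eye(3)))
        kw["translation"] = np.asarray(kw.get("translation", np.zeros(3)))
        cls = {"sphere": Sphere, "spheroid": Spheroid, "spiral": SpiralRod}[kind]
        return cls(**kw)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class Sphere(ParticleShape):
    radius: float = 1.5

    kind = "sphere"

    def _sdf_local(self, pts):
        return np.linalg.norm(pts, axis=1) - self.radius

    def sdf_gradient(self, points, h=1e-5):
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = pts - self.translation
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        return d / np.where(norm > 0, norm, 1.0)

    def surface_area(self):
        return 4.0 * np.pi * self.radius ** 2

    def volume(self):
        return 4.0 * np.pi * self.radius ** 3 / 3.0

    def surface_points_weighted(self, n):
        pts = self.to_world(_fibonacci_sphere(n) * self.radius)
        w = np.full(n, self.surface_area() / n)
        return pts, w

    def sample_surface(self, n, rng):
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return self.to_world(v * self.radius)

    def lowest_point_z(self):
        return float(self.translation[2] - self.radius)

    def vertical_extent(self):
        return 2.0 * self.radius

    def _params_dict(self):
        return {"radius": self.radius}


@dataclass
class Spheroid(ParticleShape):
    """Prolate spheroid with equatorial semi-axes r1 = r2 and polar r3 along
    the local z axis (r3 >= r1)."""

    r1: float = 1.5
    r3: float = 4.2

    kind = "spheroid"

    def __post_init__(self):
        super().__post_init__()
        if not (0 < self.r1 <= self.r3):
            raise ValueError("prolate spheroid requires 0 < r1 <= r3")

    def signed_distance(self, points):
        from . import _kernels as K

        if not K.HAVE_NUMBA:
            return super().signed_distance(points)
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        p2 = np.ascontiguousarray(np.atleast_2d(pts))
        out = np.empty(len(p2))
        K.spheroid_sdf(p2, float(self.r1), float(self.r3),
                       np.ascontiguousarray(self.rotation),
                       np.ascontiguousarray(self.translation), out)
        return float(out[0]) if single else out

    def _sdf_local(self, pts):
        a, c = self.r1, self.r3
        rho = np.hypot(pts[:, 0], pts[:, 1])
        z = np.abs(pts[:, 2])
        # nearest point on the (a, c) ellipse in the (rho, z) quadrant by
        # bisection on the parameter u: (a sin u, c cos u), u in [0, pi/2]
        lo = np.zeros_like(rho)
        hi = np.full_like(rho, np.pi / 2)
        for _ in range(48):
            u = 0.5 * (lo + hi)
            su, cu = np.sin(u), np.cos(u)
            # derivative of squared distance / 2 wrt u
            g = (a * a - c * c) * su * cu - a * rho * cu + c * z * su
            hi = np.where(g > 0, u, hi)
            lo = np.where(g > 0, lo, u)
        u = 0.5 * (lo + hi)
        dist = np.hypot(rho - a * np.sin(u), z - c * np.cos(u))
        inside = (rho / a) ** 2 + (z / c) ** 2 < 1.0
        return np.where(inside, -dist, dist)

    def surface_area(self):
        a, c = self.r1, self.r3
        if np.isclose(a, c):
            return 4.0 * np.pi * a * a
        e = np.sqrt(1.0 - (a / c) ** 2)
        return 2.0 * np.pi * a * a * (1.0 + (c / (a * e)) * np.arcsin(e))

    def local_curvature_radius(self, points):
        # nearest-point parameter u on the meridian ellipse, then the two
        # principal radii: meridian h^3/(a c) and hoop a h / c with
        # h = sqrt(a^2 cos^2 u + c^2 sin^2 u)
        a, c = self.r1, self.r3
        pts = self.to_local(np.atleast_2d(points))
        rho = np.hypot(pts[:, 0], pts[:, 1])
        z = np.abs(pts[:, 2])
        lo = np.zeros_like(rho)
        hi = np.full_like(rho, np.pi / 2)
        for _ in range(32):
            u = 0.5 * (lo + hi)
            su, cu = np.sin(u), np.cos(u)
            g = (a * a - c * c) * su * cu - a * rho * cu + c * z * su
            hi = np.where(g > 0, u, hi)
            lo = np.where(g > 0, lo, u)
        u = 0.5 * (lo + hi)
        h = np.sqrt((a * np.cos(u)) ** 2 + (c * np.sin(u)) ** 2)
        return np.minimum(h ** 3 / (a * c), a * h / c)

    def volume(self):
        return 4.0 * np.pi * self.r1 ** 2 * self.r3 / 3.0

    def surface_points_weighted(self, n):
        a, c = self.r1, self.r3
        # (u, phi) grid with area-element weights
        m_u = max(8, int(np.sqrt(n * c / (2 * a))))
        m_p = max(8, n // m_u)
        u = (np.arange(m_u) + 0.5) * np.pi / m_u
        phi = (np.arange(m_p) + 0.5) * 2 * np.pi / m_p
        uu, pp = np.meshgrid(u, phi, indexing="ij")
        su, cu = np.sin(uu), np.cos(uu)
        x = a * su * np.cos(pp)
        y = a * su * np.sin(pp)
        z = c * cu
        dA = (a * su * np.sqrt((a * cu) ** 2 + (c * su) ** 2)
              * (np.pi / m_u) * (2 * np.pi / m_p))
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        w = dA.ravel()
        w *= self.surface_area() / w.sum()
        return self.to_world(pts), w

    def sample_surface(self, n, rng):
        a, c = self.r1, self.r3
        out = []
        need = n
        gmax = c  # max of sqrt((a cos u)^2 + (c sin u)^2)
        while need > 0:
            k = max(32, 2 * need)
            u = np.arccos(1 - 2 * rng.random(k))  # sin-weighted
            g = np.sqrt((a * np.cos(u)) ** 2 + (c * np.sin(u)) ** 2)
            keep = rng.random(k) < g / gmax
            u = u[keep][:need]
            phi = rng.random(len(u)) * 2 * np.pi
            out.append(np.column_stack([
                a * np.sin(u) * np.cos(phi),
                a * np.sin(u) * np.sin(phi),
                c * np.cos(u)]))
            need -= len(u)
        return self.to_world(np.vstack(out))

    def _support_z(self) -> float:
        """Support function along world z (half the vertical extent)."""
        ax = self.rotation.T @ np.array([0.0, 0.0, 1.0])  # world z in local
        a, c = self.r1, self.r3
        return float(np.sqrt(a * a * (1 - ax[2] ** 2) + c * c * ax[2] ** 2))

    def lowest_point_z(self):
        return float(self.translation[2] - self._support_z())

    def vertical_extent(self):
        return 2.0 * self._support_z()

    def _params_dict(self):
        return {"r1": self.r1, "r3": self.r3}


@dataclass
class SpiralRod(ParticleShape):
    """Helical tube ("corkscrew") with hemispherical end caps.

    Centerline: helix of radius ``helix_radius`` and pitch ``pitch`` over
    ``n_turns`` turns, centred vertically on the local origin; the tube has
    radius ``tube_radius``.
    """

    helix_radius: float = 1.2
    pitch: float = 2.0
    tube_radius: float = 0.5
    n_turns: float = 3.0

    kind = "spiral"

    def __post_init__(self):
        super().__post_init__()
        if min(self.helix_radius, self.pitch, self.tube_radius,
               self.n_turns) <= 0:
            raise ValueError("spiral dimensions must be positive")
        if self.tube_radius >= self.pitch / 2 or \
                self.tube_radius >= self.helix_radius:
            raise ValueError("self-intersecting tube "
                             "(tube_radius must be < pitch/2 and < helix_radius)")

    # helix parameterisation -------------------------------------------

    @property
    def _t_max(self):
        return 2.0 * np.pi * self.n_turns

    @property
    def _z0(self):
        return -0.5 * self.pitch * self.n_turns

    def _centerline(self, t):
        t = np.asarray(t, dtype=np.float64)
        return np.column_stack([
            self.helix_radius * np.cos(t),
            self.helix_radius * np.sin(t),
            self._z0 + self.pitch * t / (2 * np.pi)])

    @property
    def _speed(self):
        return np.sqrt(self.helix_radius ** 2 + (self.pitch / (2 * np.pi)) ** 2)

    @property
    def centerline_length(self):
        return self._speed * self._t_max

    @property
    def _curvature(self):
        return self.helix_radius / (self.helix_radius ** 2
                                    + (self.pitch / (2 * np.pi)) ** 2)

    def _dist_to_centerline(self, pts):
        # coarse sampling then vectorised ternary refinement of t
        m = max(16, int(48 * self.n_turns))
        ts = np.linspace(0.0, self._t_max, m)
        cl = self._centerline(ts)
        d2 = ((pts[:, None, :] - cl[None, :, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        dt = ts[1] - ts[0]
        lo = np.clip(ts[best] - dt, 0.0, self._t_max)
        hi = np.clip(ts[best] + dt, 0.0, self._t_max)
        for _ in range(40):
            m1 = lo + (hi - lo) / 3
            m2 = hi - (hi - lo) / 3
            d1 = ((pts - self._centerline(m1)) ** 2).sum(axis=1)
            d2_ = ((pts - self._centerline(m2)) ** 2).sum(axis=1)
            sel = d1 < d2_
            hi = np.where(sel, m2, hi)
            lo = np.where(sel, lo, m1)
        t = 0.5 * (lo + hi)
        return np.sqrt(((pts - self._centerline(t)) ** 2).sum(axis=1))

    def _sdf_local(self, pts):
        return self._dist_to_centerline(pts) - self.tube_radius

    def surface_area(self):
        r = self.tube_radius
        return 2 * np.pi * r * self.centerline_length + 4 * np.pi * r * r

    def volume(self):
        r = self.tube_radius
        return np.pi * r * r * self.centerline_length + 4 * np.pi * r ** 3 / 3

    def local_curvature_radius(self, points):
        pts = np.atleast_2d(points)
        return np.full(len(pts), self.tube_radius)

    def _frames(self, t):
        """Tangent/normal/binormal frames along the helix."""
        rh, p = self.helix_radius, self.pitch / (2 * np.pi)
        sp = self._speed
        tang = np.column_stack([-rh * np.sin(t), rh * np.cos(t),
                                np.full_like(t, p)]) / sp
        nrm = np.column_stack([-np.cos(t), -np.sin(t), np.zeros_like(t)])
        binm = np.cross(tang, nrm)
        return tang, nrm, binm

    def surface_points_weighted(self, n):
        r = self.tube_radius
        tube_area = 2 * np.pi * r * self.centerline_length
        cap_area = 4 * np.pi * r * r
        n_tube = max(64, int(n * tube_area / (tube_area + cap_area)))
        m_t = max(16, int(np.sqrt(n_tube * self.centerline_length
                                  / (2 * np.pi * r))))
        m_p = max(8, n_tube // m_t)
        t = (np.arange(m_t) + 0.5) * self._t_max / m_t
        phi = (np.arange(m_p) + 0.5) * 2 * np.pi / m_p
        tt, pp = np.meshgrid(t, phi, indexing="ij")
        _, nrm, binm = self._frames(tt.ravel())
        cl = self._centerline(tt.ravel())
        pts = cl + r * (np.cos(pp.ravel())[:, None] * nrm
                        + np.sin(pp.ravel())[:, None] * binm)
        w = (r * self._speed * (1 - r * self._curvature * np.cos(pp.ravel()))
             * (self._t_max / m_t) * (2 * np.pi / m_p))
        # hemispherical caps
        n_cap = max(32, (n - len(pts)) // 2)
        cap_pts = []
        cap_w = []
        for t_end, sign in ((0.0, -1.0), (self._t_max, +1.0)):
            tang, _, _ = self._frames(np.array([t_end]))
            sph = _fibonacci_sphere(2 * n_cap)
            outward = sph @ (sign * tang[0]) > 0
            sph = sph[outward]
            cap_pts.append(self._centerline(np.array([t_end]))[0] + r * sph)
            cap_w.append(np.full(len(sph), 2 * np.pi * r * r / len(sph)))
        pts = np.vstack([pts] + cap_pts)
        w = np.concatenate([w] + cap_w)
        w *= self.surface_area() / w.sum()
        return self.to_world(pts), w

    def sample_surface(self, n, rng):
        pts, w = self.surface_points_weighted(max(4 * n, 2000))
        idx = rng.choice(len(pts), size=n, p=w / w.sum())
        return pts[idx]

    def vertical_extent(self):
        pts, _ = self.surface_points_weighted(4000)
        return float(pts[:, 2].max() - pts[:, 2].min())

    def _params_dict(self):
        return {"helix_radius": self.helix_radius, "pitch": self.pitch,
                "tube_radius": self.tube_radius, "n_turns": self.n_turns}


def make_spiral(volume_equivalent_radius: float,
                helix_radius: float = 1.2,
                pitch: float = 2.0,
                n_turns: float = 3.0,
                **pose) -> SpiralRod:
    """Spiral rod whose volume matches a sphere of the given radius.

    The tube radius is solved from the volume constraint
    pi r^2 L + (4/3) pi r^3 = (4/3) pi R_eq^3 and must satisfy the
    non-self-intersection bounds r < pitch/2 and r < helix_radius.
    """
    from scipy.optimize import brentq

    if n_turns <= 0 or volume_equivalent_radius <= 0:
        raise ValueError("n_turns and volume_equivalent_radius must be positive")
    target = 4.0 * np.pi * volume_equivalent_radius ** 3 / 3.0
    L = np.sqrt(helix_radius ** 2 + (pitch / (2 * np.pi)) ** 2) \
        * 2 * np.pi * n_turns

    def vol(r):
        return np.pi * r * r * L + 4 * np.pi * r ** 3 / 3 - target

    r_max = min(pitch / 2, helix_radius) * 0.999
    if vol(r_max) < 0:
        raise ValueError(
            "infeasible spiral geometry: required tube would self-intersect")
    r = brentq(vol, 1e-9, r_max, xtol=1e-12)
    return SpiralRod(helix_radius=helix_radius, pitch=pitch,
                     tube_radius=float(r), n_turns=n_turns, **pose)


def spheroid_tip_first(r1=1.5, r3=4.2) -> Spheroid:
    """Major axis normal to the cell surface at contact (along world z)."""
    return Spheroid(r1=r1, r3=r3)


def spheroid_side_on(r1=1.5, r3=4.2) -> Spheroid:
    """Major axis tangent to the cell surface at contact (along world x)."""
    return Spheroid(r1=r1, r3=r3, rotation=_rotation_x_to_z())
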