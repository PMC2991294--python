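"""Numba-accelerated inner kernels for the Monte Carlo engine.

These reimplement, loop-wise, exactly the discrete operators of
:mod:`phagozip.geometry` (Meyer mixed areas, cotangent Laplacian mean
curvature, angle-defect Gaussian curvature, divergence-theorem volume) for
the small vertex stencils touched by a trial move.  The vectorised numpy
implementations remain the reference; the Monte Carlo engine uses these
kernels when numba is importable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        if a and callable(a[0]):
            return a[0]
        return wrap


@njit(cache=True)
def ball_bfs(center, w, pos, nb_indptr, nb_idx, stamp, stamp_val, queue):
    """Vertices within Euclidean distance w of ``center`` through the
    edge-connected neighborhood.  Marks stamp[v] = stamp_val; returns the
    number of vertices written to ``queue``."""
    r2 = w * w
    cx, cy, cz = pos[center, 0], pos[center, 1], pos[center, 2]
    head = 0
    tail = 0
    queue[tail] = center
    tail += 1
    stamp[center] = stamp_val
    while head < tail:
        v = queue[head]
        head += 1
        for p in range(nb_indptr[v], nb_indptr[v + 1]):
            u = nb_idx[p]
            if stamp[u] == stamp_val:
                continue
            dx = pos[u, 0] - cx
            dy = pos[u, 1] - cy
            dz = pos[u, 2] - cz
            if dx * dx + dy * dy + dz * dz <= r2:
                stamp[u] = stamp_val
                queue[tail] = u
                tail += 1
    return tail


@njit(cache=True)
def tether_ok(support, new_pos, pos, nb_indptr, nb_idx, scale, in_sup,
              idx_of, stretch_limit):
    """False if any incident edge grows beyond its tether cap."""
    for s in range(len(support)):
        v = support[s]
        vx, vy, vz = new_pos[s, 0], new_pos[s, 1], new_pos[s, 2]
        sv = scale[v]
        for p in range(nb_indptr[v], nb_indptr[v + 1]):
            u = nb_idx[p]
            if in_sup[u]:
                k = idx_of[u]
                ux, uy, uz = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
            else:
                ux, uy, uz = pos[u, 0], pos[u, 1], pos[u, 2]
            dx = vx - ux
            dy = vy - uy
            dz = vz - uz
            d2 = dx * dx + dy * dy + dz * dz
            su = scale[u]
            cap = stretch_limit * (sv if sv > su else su)
            if d2 > cap * cap:
                ox = pos[v, 0] - pos[u, 0]
                oy = pos[v, 1] - pos[u, 1]
                oz = pos[v, 2] - pos[u, 2]
                if d2 > ox * ox + oy * oy + oz * oz + 1e-12:
                    return False
    return True


@njit(cache=True, fastmath=False)
def _vertex_fan_fields(v, pos, tris, vt_indptr, vt_idx, new_pos, in_sup,
                       idx_of, use_new, boundary, min_area):
    """Mixed area, |Laplacian|^2 ((2H)^2) and angle-defect K of vertex v,
    iterating its incident triangle fan.  ``use_new`` selects the overlay
    positions for support vertices.  Returns (A, H2, K, ok)."""
    amix = 0.0
    angsum = 0.0
    lx = 0.0
    ly = 0.0
    lz = 0.0
    for p in range(vt_indptr[v], vt_indptr[v + 1]):
        t = vt_idx[p]
        i0 = tris[t, 0]
        i1 = tris[t, 1]
        i2 = tris[t, 2]
        # rotate so corner 0 is v
        if i1 == v:
            i0, i1, i2 = i1, i2, i0
        elif i2 == v:
            i0, i1, i2 = i2, i0, i1
        if use_new and in_sup[i0]:
            k = idx_of[i0]
            ax, ay, az = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
        else:
            ax, ay, az = pos[i0, 0], pos[i0, 1], pos[i0, 2]
        if use_new and in_sup[i1]:
            k = idx_of[i1]
            bx, by, bz = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
        else:
            bx, by, bz = pos[i1, 0], pos[i1, 1], pos[i1, 2]
        if use_new and in_sup[i2]:
            k = idx_of[i2]
            cx, cy, cz = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
        else:
            cx, cy, cz = pos[i2, 0], pos[i2, 1], pos[i2, 2]
        # edges: e0 = C-B (opposite v), e1 = A-C, e2 = B-A
        e0x, e0y, e0z = cx - bx, cy - by, cz - bz
        e1x, e1y, e1z = ax - cx, ay - cy, az - cz
        e2x, e2y, e2z = bx - ax, by - ay, bz - az
        l0 = e0x * e0x + e0y * e0y + e0z * e0z
        l1 = e1x * e1x + e1y * e1y + e1z * e1z
        l2 = e2x * e2x + e2y * e2y + e2z * e2z
        # 2*area from cross(e2, -e1)
        nx_ = e2y * (-e1z) - e2z * (-e1y)
        ny_ = e2z * (-e1x) - e2x * (-e1z)
        nz_ = e2x * (-e1y) - e2y * (-e1x)
        area2 = np.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
        if area2 < 2.0 * min_area:
            return 0.0, 0.0, 0.0, False
        cot0 = (l1 + l2 - l0) / (2.0 * area2)
        cot1 = (l2 + l0 - l1) / (2.0 * area2)
        cot2 = (l0 + l1 - l2) / (2.0 * area2)
        # angle at corner 0
        angsum += np.arctan2(area2, cot0 * area2)
        # Meyer mixed area at corner 0
        if cot0 < 0.0 or cot1 < 0.0 or cot2 < 0.0:
            area = 0.5 * area2
            if cot0 < 0.0:
                amix += 0.5 * area
            else:
                amix += 0.25 * area
        else:
            amix += (l2 * cot2 + l1 * cot1) / 8.0
        # cotan Laplacian contribution at corner 0:
        # cot2*(A - B) + cot1*(A - C)
        lx += cot2 * (ax - bx) + cot1 * (ax - cx)
        ly += cot2 * (ay - by) + cot1 * (ay - cy)
        lz += cot2 * (az - bz) + cot1 * (az - cz)
    if amix <= 0.0:
        return 0.0, 0.0, 0.0, False
    inv2a = 1.0 / (2.0 * amix)
    mx = lx * inv2a
    my = ly * inv2a
    mz = lz * inv2a
    H2 = mx * mx + my * my + mz * mz
    full = np.pi if boundary else 2.0 * np.pi
    K = (full - angsum) / amix
    return amix, H2, K, True


@njit(cache=True)
def eval_move(support, new_pos, pos, tris, vt_indptr, vt_idx, nb_indptr,
              nb_idx, boundary_mask, A, H2, K, in_sup, idx_of, vstamp,
              vstamp_val, tstamp, tstamp_val, affected_buf, fields_buf,
              kappa_b, sigma, min_area, closed):
    """Stencil energy delta for a trial displacement.

    Returns (n_affected, dE_m, dV, ok).  ``affected_buf[:n]`` lists the
    vertices whose cached fields change; ``fields_buf[:n, 0:3]`` holds
    their new (A, H2, K).
    """
    ns = len(support)
    for s in range(ns):
        v = support[s]
        in_sup[v] = True
        idx_of[v] = s
    # affected = support + 1-ring
    na = 0
    for s in range(ns):
        v = support[s]
        if vstamp[v] != vstamp_val:
            vstamp[v] = vstamp_val
            affected_buf[na] = v
            na += 1
        for p in range(nb_indptr[v], nb_indptr[v + 1]):
            u = nb_idx[p]
            if vstamp[u] != vstamp_val:
                vstamp[u] = vstamp_val
                affected_buf[na] = u
                na += 1
    dE_m = 0.0
    ok = True
    for a in range(na):
        v = affected_buf[a]
        bnd = boundary_mask[v]
        A1, H21, K1, good = _vertex_fan_fields(
            v, pos, tris, vt_indptr, vt_idx, new_pos, in_sup, idx_of,
            True, bnd, min_area)
        if not good:
            ok = False
            break
        c2n = H21 - 2.0 * K1
        c2o = H2[v] - 2.0 * K[v]
        dE_m += (0.5 * kappa_b * c2n + sigma) * A1 \
            - (0.5 * kappa_b * c2o + sigma) * A[v]
        fields_buf[a, 0] = A1
        fields_buf[a, 1] = H21
        fields_buf[a, 2] = K1
    dV = 0.0
    if ok and closed:
        for s in range(ns):
            v = support[s]
            for p in range(vt_indptr[v], vt_indptr[v + 1]):
                t = vt_idx[p]
                if tstamp[t] == tstamp_val:
                    continue
                tstamp[t] = tstamp_val
                i0 = tris[t, 0]
                i1 = tris[t, 1]
                i2 = tris[t, 2]
                # old contribution
                vo = (pos[i0, 0] * (pos[i1, 1] * pos[i2, 2]
                                    - pos[i1, 2] * pos[i2, 1])
                      + pos[i0, 1] * (pos[i1, 2] * pos[i2, 0]
                                      - pos[i1, 0] * pos[i2, 2])
                      + pos[i0, 2] * (pos[i1, 0] * pos[i2, 1]
                                      - pos[i1, 1] * pos[i2, 0])) / 6.0
                if in_sup[i0]:
                    k = idx_of[i0]
                    ax, ay, az = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
                else:
                    ax, ay, az = pos[i0, 0], pos[i0, 1], pos[i0, 2]
                if in_sup[i1]:
                    k = idx_of[i1]
                    bx, by, bz = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
                else:
                    bx, by, bz = pos[i1, 0], pos[i1, 1], pos[i1, 2]
                if in_sup[i2]:
                    k = idx_of[i2]
                    cx, cy, cz = new_pos[k, 0], new_pos[k, 1], new_pos[k, 2]
                else:
                    cx, cy, cz = pos[i2, 0], pos[i2, 1], pos[i2, 2]
                vn = (ax * (by * cz - bz * cy)
                      + ay * (bz * cx - bx * cz)
                      + az * (bx * cy - by * cx)) / 6.0
                dV += vn - vo
    for s in range(ns):
        in_sup[support[s]] = False
    return na, dE_m, dV, ok


@njit(cache=True)
def vertex_normal(v, pos, tris, vt_indptr, vt_idx):
    nx_ = 0.0
    ny_ = 0.0
    nz_ = 0.0
    for p in range(vt_indptr[v], vt_indptr[v + 1]):
        t = vt_idx[p]
        i0, i1, i2 = tris[t, 0], tris[t, 1], tris[t, 2]
        ux = pos[i1, 0] - pos[i0, 0]
        uy = pos[i1, 1] - pos[i0, 1]
        uz = pos[i1, 2] - pos[i0, 2]
        wx = pos[i2, 0] - pos[i0, 0]
        wy = pos[i2, 1] - pos[i0, 1]
        wz = pos[i2, 2] - pos[i0, 2]
        nx_ += uy * wz - uz * wy
        ny_ += uz * wx - ux * wz
        nz_ += ux * wy - uy * wx
    nrm = np.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
    if nrm == 0.0:
        return 0.0, 0.0, 1.0
    return nx_ / nrm, ny_ / nrm, nz_ / nrm


@njit(cache=True)
def spheroid_sdf(pts, a, c, rot, trans, out):
    """Signed distance to a prolate spheroid (meridian-ellipse bisection)."""
    n = len(pts)
    for i in range(n):
        x = pts[i, 0] - trans[0]
        y = pts[i, 1] - trans[1]
        z = pts[i, 2] - trans[2]
        lx = rot[0, 0] * x + rot[1, 0] * y + rot[2, 0] * z
        ly = rot[0, 1] * x + rot[1, 1] * y + rot[2, 1] * z
        lz = rot[0, 2] * x + rot[1, 2] * y + rot[2, 2] * z
        rho = np.sqrt(lx * lx + ly * ly)
        zz = abs(lz)
        lo = 0.0
        hi = np.pi / 2
        for _ in range(36):
            u = 0.5 * (lo + hi)
            su = np.sin(u)
            cu = np.cos(u)
            g = (a * a - c * c) * su * cu - a * rho * cu + c * zz * su
            if g > 0.0:
                hi = u
            else:
                lo = u
        u = 0.5 * (lo + hi)
        dr = rho - a * np.sin(u)
        dz = zz - c * np.cos(u)
        d = np.sqrt(dr * dr + dz * dz)
        if (rho / a) ** 2 + (zz / c) ** 2 < 1.0:
            out[i] = -d
        else:
            out[i] = d
    return out
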