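"""Metropolis Monte Carlo engine for the ratchet-zipper model.

Trial moves are smooth membrane bumps: a random mobile vertex is chosen as
the fluctuation center, a random sign of the local surface normal as the
direction, and a lateral extension w drawn uniformly between the minimum
and maximum widths.  Vertices within (edge-connected Euclidean) distance w
of the center move by amplitude * cos^2(pi d / 2w) along the direction.
Moves placing any vertex strictly inside the rigid particle are invalid;
otherwise standard Metropolis acceptance applies with the energy change
evaluated on the local stencil.

Rectification distinguishes the two zipper modes.  Active: after every
accepted move, newly bound vertices are frozen permanently - at most one
per ligand bin, i.e. one actin-stabilised bond per particle-surface patch -
and the mesh is refined locally around the new contact within the
refinement range.  Passive: binding stays reversible; nothing is frozen
and reversals are penalised only through the +/- epsilon coverage energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TriMesh, build_sphere_mesh, refine_near_frozen, gather_csr
from .geometry import DegenerateTriangleError, triangle_areas_normals
from .energy import EnergyParams, EnergyBreakdown, LocalEnergyEvaluator, KB
from .cup import engulfed_fraction_mesh, height_profile


class SimulationStalled(Exception):
    """No mobile vertices remain (or nothing can progress)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo run configuration.

    The move geometry follows the simulation conventions: fluctuation
    amplitude 0.5 * R0, contact mesh size R0, minimum lateral width 4 * R0
    and refinement range equal to the particle radius R, with R0 the
    contact-shell width of the energy parameters.
    """

    mode: str = "active"                  # "active" | "passive"
    mesh_size: float = 0.075              # R0, um
    amplitude: float | None = None        # default 0.5 * mesh_size
    min_width: float | None = None        # default 4 * mesh_size
    max_width: float | None = None        # default 2 * refine_range
    refine_range: float = 1.5             # particle radius R, um
    temperature: float = 310.0            # K
    seed: int = 0
    max_sweeps: float = 400.0
    record_every: float = 0.25            # sweeps between records
    cell_volume_factor: float = 15.0      # cell volume / particle volume
    coarse_edge: float | None = None      # initial cell mesh edge; default R/2
    max_vertices: int = 60_000
    stretch_limit: float = 1.75           # tether: max edge growth factor
    curvature_frac: float | None = 0.45   # local refinement target as a
                                          # fraction of the particle's
                                          # local curvature radius
    stall_window: float = 3.0             # sweeps without contact growth
    stop_on_stall: bool = True
    complete_pct: float = 99.0            # engulfment percentage treated
                                          # as completed uptake
    direction_mode: str = "normal"        # "normal" | "z" (planar patches)
    record_profiles: bool = False

    def __post_init__(self):
        if self.mode not in ("active", "passive"):
            raise ValueError("mode must be 'active' or 'passive'")
        if self.mesh_size <= 0:
            raise ValueError("mesh_size must be positive")
        amp = self.amplitude if self.amplitude is not None \
            else 0.5 * self.mesh_size
        wmin = self.min_width if self.min_width is not None \
            else 4.0 * self.mesh_size
        wmax = self.max_width if self.max_width is not None \
            else 2.0 * self.refine_range
        if not (0 < wmin <= wmax):
            raise ValueError("need 0 < min_width <= max_width")
        if amp <= 0:
            raise ValueError("amplitude must be positive")

    def resolved(self) -> "SimulationConfig":
        """Fill derived defaults (amplitude 0.5 R0, min width 4 R0, ...)."""
        return replace(
            self,
            amplitude=self.amplitude if self.amplitude is not None
            else 0.5 * self.mesh_size,
            min_width=self.min_width if self.min_width is not None
            else 4.0 * self.mesh_size,
            max_width=self.max_width if self.max_width is not None
            else 2.0 * self.refine_range,
            coarse_edge=self.coarse_edge if self.coarse_edge is not None
            else 0.5 * self.refine_range,
        )


@dataclass
class SimulationState:
    """Mesh + energies + Monte Carlo bookkeeping for one trajectory."""

    mesh: TriMesh
    shape: object
    params: EnergyParams
    config: SimulationConfig
    rng: np.random.Generator
    evaluator: LocalEnergyEvaluator = None
    sweep: int = 0
    trials: int = 0
    accepted: int = 0
    records: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    vertex_scale: np.ndarray = None       # per-vertex birth edge scale
    _mobile: np.ndarray = None
    _refine_pending: bool = False
    _center_done: np.ndarray = None       # vertices already used as
                                          # refinement centers
    _bound_area_max: float = 0.0
    _last_growth_sweep: int = 0

    def __post_init__(self):
        if self.evaluator is None:
            cfg = self.config.resolved()
            self.evaluator = LocalEnergyEvaluator(
                self.mesh, self.shape, self.params,
                bin_size=max(self.params.R0, cfg.mesh_size))
        n = self.mesh.n_vertices
        if self.vertex_scale is None:
            self.vertex_scale = np.full(n, self.config.resolved().coarse_edge)
        if self._center_done is None:
            self._center_done = np.zeros(n, dtype=bool)
        self._update_mobile()
        self._idx_of = np.zeros(n, dtype=np.int64)
        self._in_support = np.zeros(n, dtype=bool)

    def _update_mobile(self):
        self._mobile = np.flatnonzero(~self.mesh.frozen
                                      & ~self.mesh.boundary_tag)

    @property
    def n_mobile(self) -> int:
        return len(self._mobile)

    def energy(self) -> EnergyBreakdown:
        return self.evaluator.breakdown()

    def bound_area(self) -> float:
        """Particle surface area currently covered by bound membrane."""
        ev = self.evaluator
        if ev.bins is None:
            return 0.0
        return float(ev.bins.areas[ev.bin_counts > 0].sum())


# -- state construction ---------------------------------------------------


def setup_state(shape, params: EnergyParams, config: SimulationConfig,
                ) -> SimulationState:
    """Closed quasi-spherical cell with the particle tangent at its top pole.

    The cell volume is ``cell_volume_factor`` times the particle volume
    (particles are much smaller than the cell); the preferred volume V0 is
    the initial discrete enclosed volume so the volume constraint starts
    unstressed.  The mesh is pre-refined to the contact mesh size around
    the initial contact point.
    """
    config = config.resolved()
    cell_volume = config.cell_volume_factor * shape.volume()
    cell_radius = (3.0 * cell_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    mesh = build_sphere_mesh(cell_radius, config.coarse_edge)
    shape.place_above(cell_radius, gap=0.0)
    # pre-refine around the initial contact point
    sdf = shape.signed_distance(mesh.vertices)
    seed_vertex = np.array([int(np.argmin(sdf))])
    n_coarse = mesh.n_vertices
    parents = []
    mesh = refine_near_frozen(mesh, seed_vertex, config.refine_range,
                              config.mesh_size, shape=shape,
                              shell_offset=0.3 * params.R0,
                              max_vertices=config.max_vertices,
                              parents_out=parents,
                              vertex_scale=np.full(n_coarse,
                                                   config.coarse_edge),
                              curvature_frac=config.curvature_frac)
    from .geometry import enclosed_volume

    params = params.with_(V0=enclosed_volume(mesh),
                          temperature=config.temperature)
    rng = np.random.default_rng(config.seed)
    scale = _extend_scales(
        np.full(n_coarse, config.coarse_edge), parents, mesh.vertices)
    state = SimulationState(mesh, shape, params, config, rng,
                            vertex_scale=scale)
    state._center_done = np.zeros(mesh.n_vertices, dtype=bool)
    state._center_done[seed_vertex] = True
    apply_rectification(state)
    return state


def _extend_scales(scale: np.ndarray, parents: list,
                   positions: np.ndarray) -> np.ndarray:
    """Birth scales for refinement midpoints: half the parent edge."""
    for block in parents:
        a, b = block[:, 0], block[:, 1]
        new = 0.5 * np.linalg.norm(positions[a] - positions[b], axis=1)
        scale = np.concatenate([scale, new])
    return scale


# -- move machinery -------------------------------------------------------


def _vertex_normal(state: SimulationState, vertex: int) -> np.ndarray:
    mesh = state.mesh
    indptr, tri_ids = mesh.vertex_triangles_csr
    tris = tri_ids[indptr[vertex]:indptr[vertex + 1]]
    areas, normals = triangle_areas_normals(mesh.vertices,
                                            mesh.triangles[tris])
    n = (areas[:, None] * normals).sum(axis=0)
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else np.array([0.0, 0.0, 1.0])


def propose_fluctuation(state: SimulationState, rng: np.random.Generator):
    """One trial membrane fluctuation.

    Returns (support_ids, new_positions) or None when the move is invalid
    (hard-core overlap with the particle).  Raises SimulationStalled when
    no mobile vertex remains.
    """
    cfg = state.config.resolved()
    if state.n_mobile == 0:
        raise SimulationStalled("all vertices frozen")
    mesh = state.mesh
    center = int(state._mobile[rng.integers(state.n_mobile)])
    sign = 1.0 if rng.random() < 0.5 else -1.0
    w = rng.uniform(cfg.min_width, cfg.max_width)
    if cfg.direction_mode == "z":
        direction = np.array([0.0, 0.0, sign])
    else:
        direction = sign * _vertex_normal(state, center)
    ball = mesh.geodesic_ball(center, w)
    support = ball[~mesh.frozen[ball] & ~mesh.boundary_tag[ball]]
    if not len(support):
        return None
    d = np.linalg.norm(mesh.vertices[support] - mesh.vertices[center], axis=1)
    amp = cfg.amplitude * np.cos(np.pi * d / (2.0 * w)) ** 2
    new_pos = mesh.vertices[support] + amp[:, None] * direction
    if state.shape is not None:
        # hard core: no vertex may enter the particle
        cand = state.evaluator.sdf[support] < cfg.amplitude * 1.0001
        if np.any(cand):
            if np.any(state.shape.signed_distance(new_pos[cand]) < 0.0):
                return None
    return support, new_pos


def metropolis_accept(delta_E: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/kT)); at T = 0 accept only
    energy-non-increasing moves."""
    if delta_E <= 0.0:
        return True
    if temperature <= 0.0:
        return False
    return rng.random() < np.exp(-delta_E / (KB * temperature))


def apply_rectification(state: SimulationState):
    """Active zipper: permanently freeze bound vertices, at most one per
    ligand bin (the first vertex to claim a particle-surface patch).
    Passive zipper: no-op."""
    if state.config.mode != "active" or state.shape is None:
        return
    ev = state.evaluator
    newly = ev.bound & ~state.mesh.frozen
    if not np.any(newly):
        return
    if getattr(state, "_bin_has_frozen", None) is None:
        state._bin_has_frozen = np.zeros(ev.bins.n, dtype=bool)
    cand = np.flatnonzero(newly)
    b = ev.vertex_bin[cand]
    ub, first = np.unique(b, return_index=True)
    new_bins = ~state._bin_has_frozen[ub]
    if not np.any(new_bins):
        return
    chosen = cand[first[new_bins]]
    state._bin_has_frozen[ub[new_bins]] = True
    state.mesh.frozen[chosen] = True
    state._update_mobile()
    state._refine_pending = True


def _violates_tether(state: SimulationState, support, new_pos) -> bool:
    """True if the move would grow any incident edge beyond its tether cap
    (stretch_limit times the larger endpoint birth scale).  Shrinking, and
    edges already over their cap that do not grow, are always allowed."""
    mesh = state.mesh
    indptr, nbrs = mesh.neighbors_csr
    counts = indptr[support + 1] - indptr[support]
    u = gather_csr(indptr, nbrs, support)
    v = np.repeat(support, counts)
    idx_of, in_sup = state._idx_of, state._in_support
    idx_of[support] = np.arange(len(support))
    in_sup[support] = True
    pos = mesh.vertices
    safe = np.where(in_sup[u], idx_of[u], 0)
    pu = np.where(in_sup[u, None], new_pos[safe], pos[u])
    pv = new_pos[idx_of[v]]
    in_sup[support] = False
    dnew = np.linalg.norm(pv - pu, axis=1)
    sc = state.vertex_scale
    cap = state.config.stretch_limit * np.maximum(sc[v], sc[u])
    over = dnew > cap
    if not np.any(over):
        return False
    dold = np.linalg.norm(pos[v[over]] - pos[u[over]], axis=1)
    return bool(np.any(dnew[over] > dold + 1e-12))


def step(state: SimulationState) -> bool:
    """One trial move; returns True if accepted."""
    from . import _kernels as K

    if not K.HAVE_NUMBA:
        return _step_reference(state)
    state.trials += 1
    ev = state.evaluator
    mesh = state.mesh
    cfg = state.config if state.config.amplitude is not None \
        else state.config.resolved()
    rng = state.rng
    if state.n_mobile == 0:
        raise SimulationStalled("all vertices frozen")
    center = int(state._mobile[rng.integers(state.n_mobile)])
    sign = 1.0 if rng.random() < 0.5 else -1.0
    w = rng.uniform(cfg.min_width, cfg.max_width)
    nb_indptr, nb_idx = mesh.neighbors_csr
    vt_indptr, vt_idx = mesh.vertex_triangles_csr
    pos = mesh.vertices
    ev._stamp_val += 1
    cnt = K.ball_bfs(center, w, pos, nb_indptr, nb_idx, ev._vstamp,
                     ev._stamp_val, ev._queue)
    ball = ev._queue[:cnt]
    support = ball[~mesh.frozen[ball] & ~mesh.boundary_tag[ball]]
    if not len(support):
        return False
    diff = pos[support] - pos[center]
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    amp = cfg.amplitude * np.cos(np.pi * d / (2.0 * w)) ** 2
    if cfg.direction_mode == "z":
        new_pos = pos[support].copy()
        new_pos[:, 2] += sign * amp
    elif cfg.direction_mode == "vnormal":
        # displace each vertex along its own surface normal: bumps follow
        # the local sheet orientation and can curl around the cup rim
        nrm = np.empty((len(support), 3))
        for i_, v_ in enumerate(support):
            nrm[i_] = K.vertex_normal(int(v_), pos, mesh.triangles,
                                      vt_indptr, vt_idx)
        new_pos = pos[support] + (sign * amp)[:, None] * nrm
    else:
        nxv, nyv, nzv = K.vertex_normal(center, pos, mesh.triangles,
                                        vt_indptr, vt_idx)
        direction = sign * np.array([nxv, nyv, nzv])
        new_pos = pos[support] + amp[:, None] * direction
    shape = state.shape
    sdf_sup = None
    maybe = None
    if shape is not None:
        # vertices that might touch or enter the shell need a fresh
        # signed distance; the rest keep a conservative lower bound
        maybe = ev.sdf[support] < cfg.amplitude + state.params.R0
        sdf_sup = ev.sdf[support] - amp  # lower-bound proxy
        if np.any(maybe):
            exact = shape.signed_distance(new_pos[maybe])
            if np.any(exact < 0.0):
                return False
            sdf_sup[maybe] = exact
    if not K.tether_ok(support, new_pos, pos, nb_indptr, nb_idx,
                       state.vertex_scale, ev._in_sup, ev._idx_sup,
                       cfg.stretch_limit):
        return False
    ev._stamp_val += 1
    na, dE_m, dV, ok = K.eval_move(
        support, new_pos, pos, mesh.triangles, vt_indptr, vt_idx,
        nb_indptr, nb_idx, ev._bnd_mask, ev.vertex_area, ev._H2, ev._K,
        ev._in_sup, ev._idx_sup, ev._vstamp, ev._stamp_val, ev._tstamp,
        ev._stamp_val, ev._affected_buf, ev._fields_buf,
        state.params.kappa_b, state.params.sigma, 1e-6, ev._closed)
    if not ok:
        return False
    from .energy import volume_energy

    dE_vol = (volume_energy(ev.V + dV, state.params)
              - volume_energy(ev.V, state.params)) if ev._closed else 0.0
    # contact delta on the particle-surface bins
    dE_lr = 0.0
    touched = None
    if shape is not None:
        bins_sup = np.full(len(support), -1, dtype=np.int64)
        bound_sup = np.zeros(len(support), dtype=bool)
        if np.any(maybe):
            sd = sdf_sup[maybe]
            bd = (sd >= 0.0) & (sd < state.params.R0)
            bound_sup[maybe] = bd
            if np.any(bd):
                sel = np.flatnonzero(maybe)[bd]
                bins_sup[sel] = ev.bins.assign(new_pos[sel])
        old_bins = ev.vertex_bin[support]
        rem = old_bins[old_bins >= 0]
        add = bins_sup[bins_sup >= 0]
        if len(rem) or len(add):
            touched = np.unique(np.concatenate([rem, add]))
            cnt_old = ev.bin_counts[touched]
            cnt_new = (cnt_old
                       - np.bincount(np.searchsorted(touched, rem),
                                     minlength=len(touched))
                       + np.bincount(np.searchsorted(touched, add),
                                     minlength=len(touched)))
            dE_lr = float(-state.params.epsilon * (
                ev.bins.areas[touched]
                * ((cnt_new > 0).astype(float)
                   - (cnt_old > 0).astype(float))).sum())
    dE = dE_m + dE_vol + dE_lr
    if not metropolis_accept(dE, state.params.temperature, rng):
        return False
    # commit
    pos[support] = new_pos
    aff = ev._affected_buf[:na]
    ev.vertex_area[aff] = ev._fields_buf[:na, 0]
    ev._H2[aff] = ev._fields_buf[:na, 1]
    ev._K[aff] = ev._fields_buf[:na, 2]
    ev.E_m += dE_m
    ev.V += dV
    ev.E_LR += dE_lr
    if shape is not None:
        # proxy for far vertices, exact where it matters: the cache is a
        # lower bound, refreshed whenever a vertex nears the shell
        ev.sdf[support] = sdf_sup
        ev.bound[support] = bound_sup
        ev.vertex_bin[support] = bins_sup
        if touched is not None:
            ev.bin_counts[touched] = cnt_new
    state.accepted += 1
    apply_rectification(state)
    return True


def _step_reference(state: SimulationState) -> bool:
    """Reference (pure numpy) trial move; same semantics as :func:`step`."""
    state.trials += 1
    prop = propose_fluctuation(state, state.rng)
    if prop is None:
        return False
    support, new_pos = prop
    if _violates_tether(state, support, new_pos):
        return False
    try:
        dE, commit = state.evaluator.evaluate(support, new_pos)
    except DegenerateTriangleError:
        return False
    if not metropolis_accept(dE, state.params.temperature, state.rng):
        return False
    commit()
    state.accepted += 1
    apply_rectification(state)
    return True


def _maybe_refine(state: SimulationState):
    """One-shot local refinement around newly bound/frozen vertices.

    Each contact vertex triggers refinement of its surroundings (within the
    refinement range) exactly once; already-resolved territory is not
    re-split when it stretches (the tether bounds stretching instead)."""
    cfg = state.config.resolved()
    centers = np.flatnonzero(
        (state.evaluator.bound | state.mesh.frozen) & ~state._center_done)
    state._refine_pending = False
    if not len(centers):
        return
    n_before = state.mesh.n_vertices
    parents = []
    new_mesh = refine_near_frozen(
        state.mesh, centers, cfg.refine_range, cfg.mesh_size,
        shape=state.shape, shell_offset=0.3 * state.params.R0,
        max_vertices=cfg.max_vertices, parents_out=parents,
        vertex_scale=state.vertex_scale,
        curvature_frac=cfg.curvature_frac)
    done = state._center_done.copy()
    done[centers] = True
    if new_mesh.n_vertices == n_before:
        state._center_done = done
        return
    state.vertex_scale = _extend_scales(state.vertex_scale, parents,
                                        new_mesh.vertices)
    n_new = new_mesh.n_vertices
    state._center_done = np.concatenate(
        [done, np.zeros(n_new - n_before, dtype=bool)])
    state.mesh = new_mesh
    state.evaluator.mesh = new_mesh
    state.evaluator.rebuild()
    state._update_mobile()
    state._idx_of = np.zeros(n_new, dtype=np.int64)
    state._in_support = np.zeros(n_new, dtype=bool)
    apply_rectification(state)


@dataclass
class Trajectory:
    """Recorded time course of one simulation run."""

    records: list
    profiles: list
    state: SimulationState

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def engulfment_at(self, sweep: float) -> float:
        """Engulfed % at a sweep count (step interpolation, last record
        carried forward)."""
        sweeps = np.array([r["sweep"] for r in self.records])
        eng = np.array([r["engulfed_pct"] for r in self.records])
        if sweep <= sweeps[0]:
            return float(eng[0])
        return float(np.interp(sweep, sweeps, eng))

    def first_crossing(self, pct: float) -> float | None:
        """First sweep at which engulfment reaches ``pct`` (interpolated)."""
        sweeps = np.array([r["sweep"] for r in self.records])
        eng = np.array([r["engulfed_pct"] for r in self.records])
        above = np.flatnonzero(eng >= pct)
        if not len(above):
            return None
        i = above[0]
        if i == 0:
            return float(sweeps[0])
        s0, s1 = sweeps[i - 1], sweeps[i]
        e0, e1 = eng[i - 1], eng[i]
        if e1 == e0:
            return float(s1)
        return float(s0 + (pct - e0) * (s1 - s0) / (e1 - e0))


def _record(state: SimulationState):
    eng = engulfed_fraction_mesh(state.mesh, state.shape, state.params.R0) \
        if state.shape is not None else 0.0
    e = state.energy()
    rec = {
        "sweep": state.sweep,
        "E_m": e.E_m,
        "E_vol": e.E_vol,
        "E_LR": e.E_LR,
        "E_total": e.E_total,
        "engulfed_pct": eng,
        "n_vertices": state.mesh.n_vertices,
        "n_frozen": int(state.mesh.frozen.sum()),
        "acceptance": state.accepted / max(1, state.trials),
    }
    state.records.append(rec)
    if state.config.record_profiles and state.shape is not None:
        state.profiles.append(
            (state.sweep,
             height_profile(state.mesh, state.shape, state.params.R0)))
    return rec


def run(config: SimulationConfig, params: EnergyParams, shape,
        state: SimulationState | None = None) -> Trajectory:
    """Run the zipper simulation to completion, stall, or the sweep budget.

    One sweep is (current mobile-vertex count) trial moves.  Records
    engulfment percentage and the energy breakdown every ``record_every``
    sweeps; terminates at >= 99% engulfment, after ``max_sweeps``, or when
    the contact zone has not grown for ``stall_window`` sweeps (if
    ``stop_on_stall``).
    """
    config = config.resolved()
    if state is None:
        state = setup_state(shape, params, config)
    rec = _record(state)
    while state.sweep < config.max_sweeps:
        n_mob = max(1, state.n_mobile)
        block = max(1, int(round(config.record_every * n_mob)))
        try:
            for _ in range(block):
                step(state)
        except SimulationStalled:
            break
        state.sweep += block / n_mob
        if state._refine_pending:
            _maybe_refine(state)
        ba = state.bound_area()
        if ba > state._bound_area_max + 1e-12:
            state._bound_area_max = ba
            state._last_growth_sweep = state.sweep
        rec = _record(state)
        if rec["engulfed_pct"] >= config.complete_pct:
            break
        if config.stop_on_stall and \
                state.sweep - state._last_growth_sweep > config.stall_window:
            break
    if state.records[-1]["sweep"] != state.sweep:
        rec = _record(state)
    return Trajectory(state.records, state.profiles, state)


def calibrate_time(trajectories, pct: float = 50.0,
                   minutes: float = 6.0) -> float:
    """Sweeps-per-minute factor from reference active small-particle runs.

    The sweep count at which the reference trajectories reach ``pct``
    engulfment (median over runs) is identified with ``minutes`` of real
    time; the factor is reused unchanged for all other conditions.
    """
    crossings = []
    for tr in trajectories:
        c = tr.first_crossing(pct)
        if c is not None:
            crossings.append(c)
    if not crossings:
        raise ValueError(
            f"no reference trajectory reached {pct}% engulfment")
    return float(np.median(crossings) / minutes)
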