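"""Monte Carlo engine mechanics on small, fast configurations."""

import numpy as np
import pytest

from phagozip import (
    Sphere, SimulationConfig, metropolis_accept, standard_parameters,
    calibrate_time,
)
from phagozip.simulate import (
    setup_state, step, propose_fluctuation, apply_rectification,
    SimulationStalled, run, Trajectory,
)


def tiny_setup(mode="active", seed=3, **overrides):
    """Small, quick simulation state for mechanics tests."""
    shape = Sphere(radius=1.2)
    params = standard_parameters(1.2).with_(R0=0.095 * 1.2)
    kw = dict(mode=mode, mesh_size=0.18 * 1.2, refine_range=1.2,
              min_width=4 * params.R0, max_width=1.2, coarse_edge=0.6,
              seed=seed, stretch_limit=5.0, max_sweeps=10.0,
              record_every=0.5, stop_on_stall=False)
    kw.update(overrides)
    config = SimulationConfig(**kw).resolved()
    return setup_state(shape, params, config), config


class TestMetropolis:
    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, 310.0, rng) for _ in range(50))

    def test_ln2_accepted_half_the_time(self, rng):
        from phagozip.energy import KB

        dE = KB * 310.0 * np.log(2.0)
        acc = np.mean([metropolis_accept(dE, 310.0, rng)
                       for _ in range(4000)])
        assert acc == pytest.approx(0.5, abs=0.03)

    def test_zero_temperature_rejects_uphill(self, rng):
        assert not any(metropolis_accept(1e-9, 0.0, rng)
                       for _ in range(20))
        assert metropolis_accept(-1e-9, 0.0, rng)


class TestProposals:
    def test_amplitude_is_half_mesh_size(self):
        state, config = tiny_setup()
        rng = np.random.default_rng(0)
        amps = []
        for _ in range(30):
            prop = propose_fluctuation(state, rng)
            if prop is None:
                continue
            support, new_pos = prop
            disp = np.linalg.norm(new_pos - state.mesh.vertices[support],
                                  axis=1)
            amps.append(disp.max())
        assert max(amps) <= 0.5 * config.mesh_size + 1e-12
        assert max(amps) > 0.4 * config.mesh_size  # center moves ~fully

    def test_support_excludes_frozen(self):
        state, config = tiny_setup()
        state.mesh.frozen[:] = False
        state.mesh.frozen[::2] = True
        state._update_mobile()
        rng = np.random.default_rng(1)
        for _ in range(10):
            prop = propose_fluctuation(state, rng)
            if prop is None:
                continue
            support, _ = prop
            assert not np.any(state.mesh.frozen[support])

    def test_all_frozen_raises_stall(self):
        state, _ = tiny_setup()
        state.mesh.frozen[:] = True
        state._update_mobile()
        with pytest.raises(SimulationStalled):
            propose_fluctuation(state, np.random.default_rng(0))

    def test_hardcore_never_violated_after_steps(self):
        state, _ = tiny_setup()
        for _ in range(300):
            step(state)
        sdf = state.shape.signed_distance(state.mesh.vertices)
        assert sdf.min() >= -1e-9


class TestRectification:
    def test_passive_mode_never_freezes(self):
        state, _ = tiny_setup(mode="passive")
        n0 = int(state.mesh.frozen.sum())
        assert n0 == 0
        for _ in range(300):
            step(state)
        assert int(state.mesh.frozen.sum()) == 0

    def test_active_frozen_set_monotone(self):
        state, _ = tiny_setup(mode="active")
        counts = []
        for _ in range(20):
            for _ in range(50):
                step(state)
            counts.append(int(state.mesh.frozen.sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_frozen_vertices_are_in_contact_shell(self):
        state, _ = tiny_setup(mode="active")
        for _ in range(300):
            step(state)
        frozen = state.mesh.frozen
        sdf = state.shape.signed_distance(state.mesh.vertices[frozen])
        assert np.all(sdf < state.params.R0 + 1e-9)


class TestDeterminism:
    def test_same_seed_identical_trajectories(self):
        shape1 = Sphere(radius=1.2)
        shape2 = Sphere(radius=1.2)
        params = standard_parameters(1.2).with_(R0=0.095 * 1.2)
        kw = dict(mode="active", mesh_size=0.18 * 1.2, refine_range=1.2,
                  min_width=4 * params.R0, max_width=1.2, coarse_edge=0.6,
                  seed=7, stretch_limit=5.0, max_sweeps=3.0,
                  record_every=0.5, stop_on_stall=False)
        tr1 = run(SimulationConfig(**kw), params, shape1)
        tr2 = run(SimulationConfig(**kw), params, shape2)
        e1 = [r["E_total"] for r in tr1.records]
        e2 = [r["E_total"] for r in tr2.records]
        assert e1 == e2
        assert np.array_equal(tr1.state.mesh.vertices,
                              tr2.state.mesh.vertices)

    def test_different_seeds_differ(self):
        shape1 = Sphere(radius=1.2)
        shape2 = Sphere(radius=1.2)
        params = standard_parameters(1.2).with_(R0=0.095 * 1.2)
        kw = dict(mode="active", mesh_size=0.18 * 1.2, refine_range=1.2,
                  min_width=4 * params.R0, max_width=1.2, coarse_edge=0.6,
                  stretch_limit=5.0, max_sweeps=2.0, record_every=0.5,
                  stop_on_stall=False)
        tr1 = run(SimulationConfig(seed=1, **kw), params, shape1)
        tr2 = run(SimulationConfig(seed=2, **kw), params, shape2)
        assert tr1.records[-1]["E_total"] != tr2.records[-1]["E_total"]


class TestCalibration:
    def _fake_traj(self, crossing_sweep):
        recs = [{"sweep": s, "engulfed_pct": 100.0 * s / (2 * crossing_sweep)}
                for s in np.linspace(0, 2 * crossing_sweep, 41)]
        return Trajectory(recs, [], None)

    def test_factor_is_crossing_over_six(self):
        tr = self._fake_traj(18.0)
        assert calibrate_time([tr]) == pytest.approx(3.0)

    def test_factor_reused_median_over_repeats(self):
        trs = [self._fake_traj(12.0), self._fake_traj(18.0),
               self._fake_traj(24.0)]
        assert calibrate_time(trs) == pytest.approx(3.0)

    def test_error_when_reference_never_crosses(self):
        recs = [{"sweep": s, "engulfed_pct": 10.0} for s in range(5)]
        with pytest.raises(ValueError):
            calibrate_time([Trajectory(recs, [], None)])


class TestRunLoop:
    def test_records_schema_and_energy_consistency(self):
        from phagozip.energy import (membrane_energy, contact_energy,
                                     volume_energy)
        from phagozip.geometry import enclosed_volume

        state, config = tiny_setup(max_sweeps=2.0)
        tr = run(config, state.params, state.shape, state=state)
        rec = tr.records[-1]
        for key in ("sweep", "E_m", "E_vol", "E_LR", "E_total",
                    "engulfed_pct", "n_frozen", "acceptance"):
            assert key in rec
        ev = tr.state.evaluator
        assert abs(ev.E_m - membrane_energy(tr.state.mesh,
                                            tr.state.params)) < 1e-8
        assert abs(ev.E_LR - contact_energy(tr.state.mesh, tr.state.shape,
                                            tr.state.params,
                                            bins=ev.bins)) < 1e-8
        assert abs(ev.V - enclosed_volume(tr.state.mesh)) < 1e-8

    def test_engulfment_interpolation(self):
        recs = [{"sweep": 0.0, "engulfed_pct": 0.0},
                {"sweep": 10.0, "engulfed_pct": 50.0}]
        tr = Trajectory(recs, [], None)
        assert tr.engulfment_at(5.0) == pytest.approx(25.0)
        assert tr.first_crossing(25.0) == pytest.approx(5.0)
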