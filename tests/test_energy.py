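"""Energy components, unit conventions and delta-energy consistency."""

import numpy as np
import pytest

from phagozip import (
    build_sphere_mesh, build_flat_patch, Sphere,
    membrane_energy, volume_energy, contact_energy, total_energy,
    delta_energy, standard_parameters, EnergyParams, KB,
)
from phagozip.energy import LocalEnergyEvaluator, ContactBins
from phagozip.geometry import enclosed_volume


class TestUnits:
    def test_boltzmann_at_body_temperature(self):
        assert KB * 310.0 == pytest.approx(4.28e-3, rel=1e-3)

    def test_sigma_unit_conversion(self):
        p = standard_parameters()
        # 6.2e-6 mN/m = 6.2e-3 pN/um
        assert p.sigma == pytest.approx(6.2e-3)

    def test_standard_parameter_values(self):
        p = standard_parameters(1.5)
        assert p.kappa_b == pytest.approx(1.3e-2)
        assert p.kappa_P == pytest.approx(2.56e-5)
        assert p.epsilon == pytest.approx(58.5)
        assert p.R0 < 0.1 * 1.5

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            EnergyParams(kappa_b=-1.0)


class TestMembraneEnergy:
    def test_sphere_bending_energy_4pi_kappa(self, unit_icosphere):
        p = standard_parameters().with_(sigma=0.0)
        e = membrane_energy(unit_icosphere, p)
        assert e == pytest.approx(4 * np.pi * p.kappa_b, rel=0.02)

    def test_flat_patch_tension_only(self):
        patch = build_flat_patch(4.0, 0.5)
        p = standard_parameters().with_(kappa_b=0.0)
        from phagozip.geometry import vertex_areas

        assert membrane_energy(patch, p) == pytest.approx(
            p.sigma * vertex_areas(patch).sum(), rel=1e-12)

    def test_sphere_full_standard_arithmetic(self):
        mesh = build_sphere_mesh(1.5, 0.1)
        p = standard_parameters(1.5)
        expected = 4 * np.pi * p.kappa_b + p.sigma * 4 * np.pi * 1.5 ** 2
        assert membrane_energy(mesh, p) == pytest.approx(expected, rel=0.02)


class TestVolumeEnergy:
    def test_zero_at_reference(self):
        p = standard_parameters().with_(V0=100.0)
        assert volume_energy(100.0, p) == 0.0

    def test_printed_arithmetic(self):
        p = standard_parameters().with_(V0=0.0)
        assert volume_energy(100.0, p) == pytest.approx(0.256)

    def test_symmetric(self):
        p = standard_parameters().with_(V0=50.0)
        assert volume_energy(80.0, p) == pytest.approx(volume_energy(20.0, p))


class TestContactEnergy:
    def test_no_contact_zero(self, unit_icosphere, sp_params):
        far = Sphere(radius=1.5)
        far.translation = np.array([0.0, 0.0, 50.0])
        assert contact_energy(unit_icosphere, far, sp_params) == 0.0

    def test_fully_wrapped_sphere(self):
        # membrane concentric with the particle, in the middle of the shell
        p = standard_parameters(1.5)
        particle = Sphere(radius=1.5)
        membrane = build_sphere_mesh(1.5 + 0.5 * p.R0, 0.05)
        e = contact_energy(membrane, particle, p)
        assert e == pytest.approx(-p.epsilon * 4 * np.pi * 1.5 ** 2,
                                  rel=0.03)

    def test_monotone_in_coverage(self):
        # lowering a flat membrane sheet onto the particle covers more
        # surface and can only decrease the contact energy
        p = standard_parameters(1.5)
        particle = Sphere(radius=1.5)
        particle.translation = np.array([0.0, 0.0, 0.0])
        bins = ContactBins(particle, p.R0)
        patch = build_flat_patch(6.0, 0.05)
        last = 0.0
        for zq in (-2.0, -1.2, -0.5, 0.0):
            # spherical cap wrapping below height zq at shell distance
            cap = build_sphere_mesh(1.5 + 0.5 * p.R0, 0.05)
            keep = cap.vertices[:, 2] <= zq
            pos = cap.vertices.copy()
            pos[~keep] *= 5.0  # move the rest far away
            from phagozip.mesh import TriMesh

            m = TriMesh(pos, cap.triangles.copy())
            e = contact_energy(m, particle, p, bins=bins)
            assert e <= last + 1e-9
            last = e

    def test_wrapping_is_thermodynamically_favourable(self):
        # adhesion gain per area exceeds bending cost per area 2*kb/R^2
        # for every radius the study considers
        p = standard_parameters()
        for R in (1.2, 1.5, 2.2, 3.0, 3.8):
            assert p.epsilon > 2 * p.kappa_b / R ** 2


class TestTotalAndDelta:
    def test_breakdown_sums_exactly(self, sp_params):
        mesh = build_sphere_mesh(3.7, 0.5)
        shape = Sphere(radius=1.5)
        shape.place_above(3.7)
        p = sp_params.with_(V0=enclosed_volume(mesh))
        b = total_energy(mesh, shape, p)
        assert b.E_total == b.E_m + b.E_vol + b.E_LR
        assert b.E_LR <= 0
        assert b.E_vol >= 0

    def test_pose_invariance_of_total_energy(self, sp_params):
        from scipy.spatial.transform import Rotation
        from phagozip.mesh import TriMesh

        mesh = build_sphere_mesh(3.7, 0.5)
        shape = Sphere(radius=1.5)
        shape.place_above(3.7)
        p = sp_params.with_(V0=enclosed_volume(mesh))
        e0 = total_energy(mesh, shape, p)
        R = Rotation.from_euler("zyx", [0.7, 0.2, -0.4]).as_matrix()
        t = np.array([1.0, -2.0, 0.5])
        moved = TriMesh(mesh.vertices @ R.T + t, mesh.triangles.copy())
        shape2 = Sphere(radius=1.5,
                        rotation=R @ shape.rotation,
                        translation=R @ shape.translation + t)
        e1 = total_energy(moved, shape2, p)
        assert e1.E_total == pytest.approx(e0.E_total, rel=1e-6)

    def test_null_displacement_zero_delta(self, sp_params):
        mesh = build_sphere_mesh(1.5, 0.2)
        shape = Sphere(radius=1.5)
        shape.place_above(1.5)
        p = sp_params.with_(V0=enclosed_volume(mesh))
        sup = np.array([0, 1, 2])
        assert delta_energy(mesh, shape, p, sup,
                            np.zeros((3, 3))) == pytest.approx(0.0)

    def test_delta_matches_global_recompute(self, sp_params, rng):
        mesh = build_sphere_mesh(1.5, 0.25)
        shape = Sphere(radius=1.5)
        shape.place_above(1.5)
        p = sp_params.with_(V0=enclosed_volume(mesh))
        ev = LocalEnergyEvaluator(mesh, shape, p)
        worst = 0.0
        for _ in range(40):
            sup = mesh.ring(np.array([rng.integers(mesh.n_vertices)]))
            newp = mesh.vertices[sup] + rng.normal(0, 0.01, (len(sup), 3))
            before = (membrane_energy(mesh, p)
                      + volume_energy(enclosed_volume(mesh), p)
                      + contact_energy(mesh, shape, p, bins=ev.bins))
            dE, commit = ev.evaluate(sup, newp)
            commit()
            after = (membrane_energy(mesh, p)
                     + volume_energy(enclosed_volume(mesh), p)
                     + contact_energy(mesh, shape, p, bins=ev.bins))
            worst = max(worst, abs(dE - (after - before)))
        assert worst < 1e-9

    def test_delta_additive_over_disjoint_supports(self, sp_params, rng):
        mesh = build_sphere_mesh(1.5, 0.25)
        shape = Sphere(radius=1.5)
        shape.place_above(1.5)
        p = sp_params.with_(V0=enclosed_volume(mesh))
        # two far-apart vertices (disjoint stencils)
        a = int(np.argmax(mesh.vertices[:, 2]))
        b = int(np.argmin(mesh.vertices[:, 2]))
        da = rng.normal(0, 0.01, (1, 3))
        db = rng.normal(0, 0.01, (1, 3))
        d_ab = delta_energy(mesh, shape, p, np.array([a, b]),
                            np.vstack([da, db]))
        d_a = delta_energy(mesh, shape, p, np.array([a]), da)
        d_b = delta_energy(mesh, shape, p, np.array([b]), db)
        assert d_ab == pytest.approx(d_a + d_b, abs=1e-9)
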