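import math
from dataclasses import replace

import numpy as np
import pytest

from flagwrap import elastic_rod as er


@pytest.fixture(scope="module")
def params():
    return er.RodParams()


class TestInit:
    def test_intrinsic_shape_has_zero_energy(self, params):
        state = er.init_rod(params, seed=0, perturbation=0.0)
        assert er.elastic_energy(state, params) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_fixed_seed_bit_identical(self, params):
        s1 = er.init_rod(params, seed=5)
        s2 = er.init_rod(params, seed=5)
        assert np.array_equal(s1.x, s2.x)
        assert np.array_equal(s1.theta, s2.theta)

    def test_clamped_edge_on_pole_axis(self, params):
        s = er.init_rod(params, seed=0, perturbation=0.0)
        assert np.allclose(s.x[0][:2], 0.0)
        assert np.allclose(s.x[1][:2], 0.0)
        assert s.x[1][2] > s.x[0][2]

    def test_initial_state_clear_of_body(self, params):
        s = er.init_rod(params, seed=0, perturbation=0.0)
        zc = params.body_length / 2 - params.body_radius
        zcl = np.clip(s.x[:, 2], -zc, zc)
        d = np.sqrt(s.x[:, 0] ** 2 + s.x[:, 1] ** 2
                    + (s.x[:, 2] - zcl) ** 2)
        assert (d[2:] > params.body_radius).all()

    def test_drag_anisotropy_validated(self):
        with pytest.raises(ValueError, match="xi_perp/xi_par"):
            er.RodParams(drag_par=0.1)


class TestForces:
    def test_forces_are_exact_energy_gradients(self, params):
        """Analytic nodal forces match central differences of the elastic
        energy (frames adapted to the current tangents)."""
        state = er.init_rod(params, seed=1, perturbation=2e-3)
        er._sync_frames(state)
        F, Gt = er.rod_forces(state, params)
        eps = 1e-7
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = int(rng.integers(0, len(state.x)))
            k = int(rng.integers(0, 3))
            sp = state.copy()
            sp.x = state.x.copy()
            sp.x[i, k] += eps
            sm = state.copy()
            sm.x = state.x.copy()
            sm.x[i, k] -= eps
            num = -(er.elastic_energy(sp, params)
                    - er.elastic_energy(sm, params)) / (2 * eps)
            assert F[i, k] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_twist_gradients_match_energy(self, params):
        state = er.init_rod(params, seed=1, perturbation=2e-3)
        er._sync_frames(state)
        _, Gt = er.rod_forces(state, params)
        eps = 1e-7
        for j in (1, 5, 20):
            sp = state.copy()
            sp.theta = state.theta.copy()
            sp.theta[j] += eps
            sm = state.copy()
            sm.theta = state.theta.copy()
            sm.theta[j] -= eps
            num = (er.elastic_energy(sp, params)
                   - er.elastic_energy(sm, params)) / (2 * eps)
            assert Gt[j] == pytest.approx(num, rel=1e-5, abs=1e-8)


class TestDynamics:
    def test_equilibrium_is_stationary(self, params):
        inter = er.BodyInteraction()
        state = er.init_rod(params, seed=0, perturbation=0.0)
        dt = er.stable_dt(params, interaction=inter)
        out = er.step_rod(state, params, inter, 0.0, dt, 10_000)
        assert np.max(np.linalg.norm(out.x - state.x, axis=1)) < 1e-4

    def test_energy_relaxes_without_drive(self, params):
        inter = er.BodyInteraction()
        state = er.init_rod(params, seed=2, perturbation=1e-3)
        dt = er.stable_dt(params, interaction=inter)
        E = [er.elastic_energy(state, params)]
        s = state
        for _ in range(4):
            s = er.step_rod(s, params, inter, 0.0, dt, 25_000)
            E.append(er.elastic_energy(s, params))
        # overall decay by orders of magnitude, monotone across checkpoints
        assert all(b <= a * 1.001 for a, b in zip(E, E[1:]))
        assert E[-1] < 1e-3 * E[0]

    def test_frame_orthonormality_preserved(self, params):
        inter = er.BodyInteraction()
        s = er.init_rod(params, seed=3, perturbation=1e-3)
        dt = er.stable_dt(params, interaction=inter)
        s = er.step_rod(s, params, inter, -300.0, dt, 50_000)
        dots = np.einsum("ij,ij->i", s.a1, s.tangents)
        norms = np.linalg.norm(s.a1, axis=1)
        assert np.abs(dots).max() < 1e-8
        assert np.abs(norms - 1).max() < 1e-8

    def test_segment_strain_stays_small(self, params):
        inter = er.BodyInteraction()
        s = er.init_rod(params, seed=0, perturbation=1e-3)
        dt = er.stable_dt(params, interaction=inter)
        s = er.step_rod(s, params, inter, -800.0, dt, 60_000)
        el = np.linalg.norm(np.diff(s.x, axis=0), axis=1)
        strain = el / s.rest["lbar"] - 1
        assert np.abs(strain).max() < 0.08

    def test_oversized_timestep_rejected(self, params):
        inter = er.BodyInteraction()
        s = er.init_rod(params, seed=0)
        with pytest.raises(ValueError, match="stability"):
            er.step_rod(s, params, inter, 0.0,
                        10 * er.stable_dt(params, 1.0, inter), 1)

    def test_clamped_free_relaxation_rate_matches_beam_theory(self):
        """A straight clamped-free rod's slowest bending mode relaxes at
        A (1.875/L)^4 / xi_perp; the simulated tip decay matches within
        15%."""
        p = er.RodParams(n_segments=24, helix_radius=1e-9,
                         helix_pitch=10.0, hook_ratio=1.0)
        inter = er.BodyInteraction(epsilon=0.0)
        s = er.init_rod(p, seed=0, perturbation=0.0)
        # deflect along the analytic clamped-free mode-1 shape (approx.:
        # tip-weighted), small amplitude
        L = 1.0 - p.segment_length
        zs = (s.x[:, 2] - s.x[1, 2]) / L
        s.x[:, 0] += 2e-3 * np.clip(zs, 0, None) ** 2
        dt = er.stable_dt(p, interaction=inter)
        rate_expected = (1.8751**4) * p.bend_stiffness / p.drag_perp / L**4
        # measure decay over a window after fast transients die out
        t_start, t_end = 0.3 / rate_expected, 1.3 / rate_expected
        s = er.step_rod(s, p, inter, 0.0, dt, int(t_start / dt))
        a0 = s.x[-1, 0]
        s = er.step_rod(s, p, inter, 0.0, dt, int((t_end - t_start) / dt))
        a1 = s.x[-1, 0]
        rate_measured = math.log(a0 / a1) / (t_end - t_start)
        assert rate_measured == pytest.approx(rate_expected, rel=0.15)


class TestClassification:
    def test_analytic_wound_helix_classified_wrapped(self, params):
        """A filament wound 2.5 turns around the body at the contact
        clearance scores as wrapped with wrap number ~2.5."""
        inter = er.BodyInteraction()
        s = er.init_rod(params, seed=0, perturbation=0.0)
        n = params.n_segments
        a, H = params.body_radius, params.body_length
        rw = a + inter.clearance
        b = params.helix_pitch / (2 * math.pi)
        zcap = H / 2 - a
        c = math.sqrt(rw**2 + b**2)
        phi = np.arange(n) * params.segment_length / c
        z = zcap + rw - b * phi
        rad = np.where(z > zcap,
                       np.sqrt(np.clip(rw**2 - (z - zcap) ** 2, 0, None)),
                       rw)
        s.x[1:, 0] = rad * np.cos(phi)
        s.x[1:, 1] = rad * np.sin(phi)
        s.x[1:, 2] = z
        out = er.classify_outcome([s], params, steady=True)
        assert out.label == "wrapped"
        assert abs(out.wrap_number) == pytest.approx(2.5, abs=0.4)

    def test_straight_trailing_filament_other(self, params):
        s = er.init_rod(replace(params, helix_radius=1e-9,
                                helix_pitch=10.0),
                        seed=0, perturbation=0.0)
        out = er.classify_outcome([s], params, steady=True)
        assert out.label == "other"
        assert out.wrap_number == pytest.approx(0.0, abs=0.05)

    def test_proximal_circle_classified_ring(self, params):
        """A planar circle hugging the attachment pole scores as ring."""
        s = er.init_rod(params, seed=0, perturbation=0.0)
        n = params.n_segments
        H = params.body_length
        um = 1.0 / er.DEFAULT_CONTOUR_UM
        r_ring = 0.3 * um
        phi = np.linspace(0, 4 * math.pi, n - 1)
        s.x[2:, 0] = r_ring * np.cos(phi)
        s.x[2:, 1] = r_ring * np.sin(phi)
        s.x[2:, 2] = H / 2 + 0.1 * um + 0.02 * um * np.arange(n - 1) / n
        out = er.classify_outcome([s], params, steady=True)
        assert out.label == "ring"

    def test_nonsteady_trajectory_refused(self, params):
        s1 = er.init_rod(params, seed=0, perturbation=0.0)
        s2 = s1.copy()
        s2.x = s1.x + 0.05
        out = er.classify_outcome([s1, s2], params)
        assert out.label == "other"
        assert not out.steady

    def test_criteria_recorded_in_outcome(self, params):
        s = er.init_rod(params, seed=0, perturbation=0.0)
        out = er.classify_outcome([s], params, steady=True)
        assert "wrap_number_min" in out.criteria
        assert "proximal_zone_um" in out.criteria


class TestDeterminism:
    def test_simulation_reproducible(self, params):
        inter = er.BodyInteraction()
        dt = er.stable_dt(params, interaction=inter)
        outs = []
        for _ in range(2):
            s = er.init_rod(params, seed=4)
            s = er.step_rod(s, params, inter, -800.0, dt, 20_000)
            outs.append(s.x.copy())
        assert np.array_equal(outs[0], outs[1])
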