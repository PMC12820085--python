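import math

import numpy as np
import pytest

from flagwrap import geometry as g
from flagwrap import hydrodynamics as hy


@pytest.fixture(scope="module")
def sphere_mesh():
    return g.build_sphere_mesh(1.0, resolution=60.0)


@pytest.fixture(scope="module")
def free_space_solutions():
    """Coarse free-space swimming solves shared across tests."""
    drive = hy.MotorDrive()
    out = {}
    for name in ("normal", "wrapped-default"):
        out[name] = hy.solve_swimming(g.preset_config(name),
                                      hy.FluidEnvironment(), drive,
                                      resolution="coarse")
    return out


class TestStokesOracles:
    def test_sphere_drag(self, sphere_mesh):
        """Translating unit sphere: drag = 6 pi mu a U within 2%."""
        mu = 1e-3
        out = hy.solve_resistance({"body": sphere_mesh},
                                  {"body": ([0, 0, 1.0], [0, 0, 0],
                                            [0, 0, 0])})
        drag = out["body"]["force"][2]
        assert drag == pytest.approx(6 * math.pi * mu, rel=0.02)

    def test_sphere_torque(self, sphere_mesh):
        """Rotating unit sphere: torque = 8 pi mu a^3 Omega within 2%."""
        mu = 1e-3
        out = hy.solve_resistance({"body": sphere_mesh},
                                  {"body": ([0, 0, 0], [0, 0, 1.0],
                                            [0, 0, 0])})
        torque = out["body"]["torque"][2]
        assert torque == pytest.approx(8 * math.pi * mu, rel=0.02)

    def test_traction_linearity(self, sphere_mesh):
        out1 = hy.solve_resistance({"body": sphere_mesh},
                                   {"body": ([0, 0, 1.0], [0, 0, 0],
                                             [0, 0, 0])})
        out2 = hy.solve_resistance({"body": sphere_mesh},
                                   {"body": ([0, 0, 2.0], [0, 0, 0],
                                             [0, 0, 0])})
        assert np.allclose(2 * out1["forces"], out2["forces"], rtol=1e-8)

    def test_resistance_matrix_spd(self):
        """Grand resistance matrix of a rigid sphere is symmetric
        positive definite (built column-wise from unit motions)."""
        mesh = g.build_sphere_mesh(0.8, resolution=40.0)
        R = np.zeros((6, 6))
        for k in range(6):
            U = np.zeros(3)
            Om = np.zeros(3)
            if k < 3:
                U[k] = 1.0
            else:
                Om[k - 3] = 1.0
            out = hy.solve_resistance({"body": mesh},
                                      {"body": (U, Om, [0, 0, 0])})
            R[:3, k] = out["body"]["force"]
            R[3:, k] = out["body"]["torque"]
        assert np.allclose(R, R.T, atol=1e-6 * np.abs(R).max())
        assert (np.linalg.eigvalsh(0.5 * (R + R.T)) > 0).all()


class TestSwimmingSolve:
    def test_no_drive_no_motion(self):
        sol = hy.solve_swimming(g.preset_config("normal"),
                                hy.FluidEnvironment(),
                                hy.MotorDrive(rate=0.0),
                                resolution="coarse")
        assert np.linalg.norm(sol.U) < 1e-10
        assert np.linalg.norm(sol.Omega) < 1e-10

    def test_force_torque_residuals(self, free_space_solutions):
        for sol in free_space_solutions.values():
            assert sol.residual_force < 1e-6
            assert sol.residual_torque < 1e-6

    def test_speed_linear_in_motor_rate(self):
        cfg = g.preset_config("normal")
        s1 = hy.solve_swimming(cfg, drive=hy.MotorDrive(rate=100.0),
                               resolution="coarse")
        s2 = hy.solve_swimming(cfg, drive=hy.MotorDrive(rate=200.0),
                               resolution="coarse")
        assert s2.speed == pytest.approx(2 * s1.speed, rel=1e-6)
        assert np.allclose(s2.Omega, 2 * s1.Omega, rtol=1e-6)

    def test_mirror_symmetry(self, free_space_solutions):
        """Flipped helix handedness at the same drive reverses the axial
        speed; magnitudes agree within mesh discretization error (the
        collocation points of the swept filament are not exact mirror
        images)."""
        cfg = g.preset_config("normal")
        mirrored = g.SwimmerConfiguration(
            "unwrapped", cfg.body,
            g.HelixShape(cfg.helix.pitch, cfg.helix.radius,
                         cfg.helix.n_turns, "right",
                         cfg.helix.taper_fraction),
            cfg.wrap_clearance, cfg.attachment_pole, cfg.filament_radius)
        sol_l = free_space_solutions["normal"]
        sol_r = hy.solve_swimming(mirrored, hy.FluidEnvironment(),
                                  hy.MotorDrive(), resolution="coarse")
        assert sol_r.speed * sol_l.speed < 0
        assert abs(sol_r.speed) == pytest.approx(abs(sol_l.speed), rel=0.03)

    def test_unwrapped_free_speed_in_biological_range(
            self, free_space_solutions):
        """At 100 Hz the unwrapped swimmer moves at tens of um/s, the
        free-swimming range observed for these species."""
        speed = abs(free_space_solutions["normal"].speed)
        assert 5.0 < speed < 50.0

    def test_motor_torque_reported(self, free_space_solutions):
        assert free_space_solutions["normal"].motor_torque != 0.0


@pytest.fixture(scope="module")
def tube_solution():
    cfg = g.preset_config("wrapped-default")
    tube = g.TubeGeometry(0.55, body_length_ref=cfg.body.length)
    return hy.solve_swimming(cfg, hy.FluidEnvironment(tube=tube),
                             hy.MotorDrive(), resolution="coarse")


class TestFlowField:

    def test_no_slip_on_wall_samples(self, tube_solution):
        sol = tube_solution
        wall = sol.labels == "wall"
        # sample points slightly inside the wall, away from elements
        pts = sol.points[wall][::40] * np.array([0.98, 0.98, 1.0])
        field = hy.compute_flow_field(sol, pts, exclusion_radius=0.0)
        speed = np.linalg.norm(field.velocity, axis=1)
        assert np.nanmedian(speed) < 0.05 * abs(sol.speed) + 1e-9

    def test_interior_points_masked(self, tube_solution):
        field = hy.compute_flow_field(tube_solution,
                                      np.array([[0.0, 0.0, 0.0]]))
        assert not field.mask[0]
        assert np.isnan(field.velocity[0]).all()

    def test_tube_truncation_end_effects_negligible(self):
        """Doubling the meshed tube length changes the confined swimming
        speed by well under 1% (open ends are far enough away)."""
        cfg = g.preset_config("wrapped-default")
        speeds = []
        for L in (25.0, 50.0):
            tube = g.TubeGeometry(0.5, truncation_length=L,
                                  body_length_ref=cfg.body.length)
            sol = hy.solve_swimming(cfg, hy.FluidEnvironment(tube=tube),
                                    hy.MotorDrive(), resolution="sweep")
            speeds.append(sol.speed)
        assert speeds[1] == pytest.approx(speeds[0], rel=0.01)

    def test_wrapped_mode_drives_gap_flow(self):
        """At a matched normalized gap, the wound filament scrapes fluid
        through the body-wall gap: the mean normalized axial velocity
        there exceeds the unwrapped mode's."""
        drive = hy.MotorDrive()
        gap_flow = {}
        for name, preset in (("unwrapped", "normal"),
                             ("wrapped", "wrapped-default")):
            cfg = g.preset_config(preset)
            R = g.max_radial_extent(cfg) + 0.1 * cfg.body.length / 2
            tube = g.TubeGeometry(R, body_length_ref=cfg.body.length)
            sol = hy.solve_swimming(cfg, hy.FluidEnvironment(tube=tube),
                                    drive, "coarse")
            rho = (cfg.body.radius + R) / 2
            zs = np.linspace(-0.9, 0.9, 13)
            phis = np.linspace(0, 2 * np.pi, 8, endpoint=False)
            pts = np.array([[rho * np.cos(p), rho * np.sin(p), z]
                            for z in zs for p in phis])
            field = hy.compute_flow_field(sol, pts, exclusion_radius=0.03)
            gap_flow[name] = np.nanmean(
                np.abs(field.axial_over_U[field.mask]))
        assert gap_flow["wrapped"] > gap_flow["unwrapped"]
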