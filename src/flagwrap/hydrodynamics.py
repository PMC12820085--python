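"""Zero-Reynolds-number mobility solver for the model swimmer.

The Stokes equations are solved with a single-layer distribution of
regularized Stokeslets collocated at surface-element centroids (one blob per
element, blob width tied to the element size and calibrated once against the
closed-form Stokes drag/torque of a sphere).  The swimmer is rigid: the
flagellum rotates as a rigid helix about the body axis at the motor rate
relative to the body, which is the time-averaged description of steady
swimming.  Inside a tube the swimmer is held coaxial with the channel.

Units: um, s, pN; viscosity in pN.s/um^2 (1 mPa.s = 1e-3 pN.s/um^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve as dense_solve

from .geometry import (
    CellBody,
    SurfaceMesh,
    SwimmerConfiguration,
    TubeGeometry,
    build_surface_meshes,
    max_radial_extent,
)

__all__ = [
    "FluidEnvironment",
    "MotorDrive",
    "MobilitySolution",
    "FlowField",
    "REG_ALPHA",
    "RESOLUTION_LADDER",
    "solve_resistance",
    "solve_swimming",
    "sweep_gap",
    "compute_flow_field",
]

#: Regularization parameter: blob width = REG_ALPHA * sqrt(element area).
#: Calibrated on the translating/rotating sphere oracle (Stokes law within
#: 2% at the reference resolution).
REG_ALPHA = 0.42

#: Documented convergence ladder: element densities (per um^2) for
#: (body, flagellum, wall).  One ladder step ~ doubles the element count.
RESOLUTION_LADDER = {
    "sweep": (45.0, 110.0, 34.0),    # reduced rung for many-solve sweeps
    "coarse": (60.0, 150.0, 45.0),
    "medium": (120.0, 300.0, 90.0),
    "fine": (240.0, 600.0, 180.0),
}

WATER_VISCOSITY = 1.0e-3  # pN.s/um^2


@dataclass(frozen=True)
class FluidEnvironment:
    """Newtonian fluid, unbounded or inside a circular tube."""

    viscosity: float = WATER_VISCOSITY
    tube: TubeGeometry | None = None

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValueError("viscosity must be > 0")


@dataclass(frozen=True)
class MotorDrive:
    """Flagellar motor: rotation of the filament relative to the body about
    the body axis.  ``sense`` is viewed from behind the flagellated pole
    (outside the cell, looking toward it): CW is the run-reversal sense that
    drives wrapping."""

    rate: float = 2 * math.pi * 100.0  # rad/s
    sense: str = "CW"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0 (sense carries the sign)")
        if self.sense not in ("CW", "CCW"):
            raise ValueError("sense must be 'CW' or 'CCW'")

    @property
    def signed_rate(self) -> float:
        """Signed rotation rate about the outward attachment-pole axis (+z)."""
        return -self.rate if self.sense == "CW" else self.rate


@dataclass
class MobilitySolution:
    """Force- and torque-free rigid-body solution for one configuration."""

    U: np.ndarray                  # swimmer translational velocity, um/s
    Omega: np.ndarray              # body angular velocity, rad/s
    motor_torque: float            # axial hydrodynamic torque on the flagellum, pN.um
    residual_force: float          # |net force| / traction scale
    residual_torque: float
    points: np.ndarray = field(repr=False, default=None)
    forces: np.ndarray = field(repr=False, default=None)   # point forces g_j, pN
    areas: np.ndarray = field(repr=False, default=None)
    eps: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    viscosity: float = WATER_VISCOSITY
    config: "SwimmerConfiguration | None" = field(repr=False, default=None)
    tube: "TubeGeometry | None" = field(repr=False, default=None)

    @property
    def speed(self) -> float:
        """Axial swimming speed (signed, um/s)."""
        return float(self.U[2])

    @property
    def tractions(self) -> np.ndarray:
        return self.forces / self.areas[:, None]


# --------------------------------------------------------------------------
# kernel and assembly
# --------------------------------------------------------------------------

def _stokeslet_blocks(targets: np.ndarray, sources: np.ndarray,
                      eps_t: np.ndarray, eps_s: np.ndarray,
                      mu: float, chunk: int = 600,
                      out: np.ndarray | None = None) -> np.ndarray:
    """Dense (3T, 3S) matrix of the regularized Stokeslet kernel.

    The pair blob width is symmetrized, eps_ij^2 = (eps_i^2 + eps_s^2)/2,
    which keeps the one-component grand resistance matrix symmetric.
    ``out`` lets the caller assemble into a preallocated (view of a)
    matrix, avoiding a full-size copy.
    """
    T, S = len(targets), len(sources)
    M = out if out is not None else np.empty((3 * T, 3 * S), order='F')
    e_s2 = eps_s**2
    pref = 1.0 / (8 * math.pi * mu)
    for i0 in range(0, T, chunk):
        i1 = min(i0 + chunk, T)
        r = targets[i0:i1, None, :] - sources[None, :, :]   # (t, S, 3)
        r2 = np.einsum("tsk,tsk->ts", r, r)
        ee = 0.5 * (eps_t[i0:i1, None] ** 2 + e_s2[None, :])
        denom = (r2 + ee) ** 1.5
        h1 = pref * (r2 + 2 * ee) / denom
        h2 = pref / denom
        blk = h2[:, :, None, None] * (r[:, :, :, None] * r[:, :, None, :])
        blk[:, :, 0, 0] += h1
        blk[:, :, 1, 1] += h1
        blk[:, :, 2, 2] += h1
        M[3 * i0:3 * i1, :] = blk.transpose(0, 2, 1, 3).reshape(
            3 * (i1 - i0), 3 * S)
    return M


def _concat_meshes(meshes: dict):
    pts, areas, labels = [], [], []
    for name, m in meshes.items():
        pts.append(m.centroids)
        areas.append(m.areas)
        labels.extend([name] * m.n_elements)
    return (np.vstack(pts), np.concatenate(areas), np.asarray(labels))


def solve_resistance(meshes: dict, boundary_velocities: dict,
                     env: FluidEnvironment | None = None,
                     return_condition: bool = False):
    """Single-layer resistance solve: prescribed rigid velocities per
    component -> point forces and net force/torque per component.

    ``boundary_velocities`` maps component name -> (U, Omega, center); the
    element velocity is U + Omega x (x - center).  Returns a dict with point
    forces, per-component force/torque, and optionally a condition-number
    estimate.
    """
    env = env or FluidEnvironment()
    pts, areas, labels = _concat_meshes(meshes)
    eps = REG_ALPHA * np.sqrt(areas)
    u = np.zeros_like(pts)
    for name, (U, Om, ctr) in boundary_velocities.items():
        sel = labels == name
        u[sel] = np.asarray(U) + np.cross(np.asarray(Om),
                                          pts[sel] - np.asarray(ctr))
    A = _stokeslet_blocks(pts, pts, eps, eps, env.viscosity)
    g = dense_solve(A, u.ravel(), overwrite_a=True,
                    check_finite=False).reshape(-1, 3)
    out = {"points": pts, "forces": g, "areas": areas, "labels": labels}
    for name in meshes:
        sel = labels == name
        out[name] = {
            "force": g[sel].sum(axis=0),
            "torque": np.cross(pts[sel], g[sel]).sum(axis=0),
        }
    if return_condition:
        out["condition"] = float(np.linalg.cond(A))
    return out


# --------------------------------------------------------------------------
# swimming (mobility) solve
# --------------------------------------------------------------------------

def solve_swimming(config: SwimmerConfiguration,
                   env: FluidEnvironment | None = None,
                   drive: MotorDrive | None = None,
                   resolution: str | tuple = "medium",
                   meshes: dict | None = None) -> MobilitySolution:
    """Solve the force- and torque-free mobility problem.

    The flagellum rotates at the signed motor rate about the body axis (+z)
    relative to the body; the unknowns are the rigid-body velocities (U,
    Omega) of the body frame and the surface point forces.  Inside a tube
    the swimmer is coaxial with the channel and the wall is a no-slip
    surface; the tube is truncated with open ends far from the swimmer.
    """
    env = env or FluidEnvironment()
    drive = drive or MotorDrive()
    if meshes is None:
        res_b, res_f, res_w = (RESOLUTION_LADDER[resolution]
                               if isinstance(resolution, str) else resolution)
        meshes = build_surface_meshes(config, env.tube, resolution=res_b,
                                      flagellum_resolution=res_f,
                                      wall_resolution=res_w)
    pts, areas, labels = _concat_meshes(meshes)
    eps = REG_ALPHA * np.sqrt(areas)
    n = len(pts)
    swim = labels != "wall"
    flag = labels == "flagellum"

    zhat = np.array([0.0, 0.0, 1.0])
    b = np.zeros((n, 3))
    b[flag] = drive.signed_rate * np.cross(zhat, pts[flag])

    # augmented system: [A  P; Q  0] [g; U, Omega] = [b; 0];
    # the kernel is assembled directly into the top-left block to keep
    # peak memory at one full-size matrix
    nA = 3 * n
    # Fortran order lets LAPACK factorize in place (no transposed copy)
    M = np.zeros((nA + 6, nA + 6), order="F")
    _stokeslet_blocks(pts, pts, eps, eps, env.viscosity,
                      out=M[:nA, :nA])
    rhs = np.zeros(nA + 6)
    rhs[:nA] = b.ravel()
    idx = np.where(swim)[0]
    for i in idx:
        r = 3 * i
        M[r:r + 3, nA:nA + 3] = -np.eye(3)
        M[r:r + 3, nA + 3:nA + 6] = _cross_matrix(pts[i])   # +[x]x Omega
        # constraint rows: force-free, torque-free over the swimmer
        M[nA:nA + 3, r:r + 3] = np.eye(3)
        M[nA + 3:nA + 6, r:r + 3] = -_cross_matrix(pts[i])  # x cross g
    sol = dense_solve(M, rhs, overwrite_a=True, check_finite=False)
    g = sol[:nA].reshape(-1, 3)
    U = sol[nA:nA + 3]
    Om = sol[nA + 3:nA + 6]

    gs = g[swim]
    net_f = gs.sum(axis=0)
    net_t = np.cross(pts[swim], gs).sum(axis=0)
    scale_f = np.abs(gs).sum()
    scale_t = float(np.abs(np.cross(pts[swim], gs)).sum())
    motor_torque = float(np.cross(pts[flag], g[flag])[:, 2].sum())
    return MobilitySolution(
        U=U, Omega=Om, motor_torque=motor_torque,
        residual_force=float(np.linalg.norm(net_f)) / max(scale_f, 1e-300),
        residual_torque=float(np.linalg.norm(net_t)) / max(scale_t, 1e-300),
        points=pts, forces=g, areas=areas, eps=eps, labels=labels,
        viscosity=env.viscosity, config=config, tube=env.tube,
    )


def _cross_matrix(x: np.ndarray) -> np.ndarray:
    """Matrix [x]_cross with [x]_cross @ v = x cross v."""
    return np.array([
        [0.0, -x[2], x[1]],
        [x[2], 0.0, -x[0]],
        [-x[1], x[0], 0.0],
    ])


# --------------------------------------------------------------------------
# gap sweep (confinement curves)
# --------------------------------------------------------------------------

def sweep_gap(config_unwrapped: SwimmerConfiguration,
              config_wrapped: SwimmerConfiguration,
              gaps, drive: MotorDrive | None = None,
              viscosity: float = WATER_VISCOSITY,
              resolution: str | tuple = "coarse",
              truncation_length: float = 25.0) -> pd.DataFrame:
    """Normalized swimming speed and angular velocity vs normalized gap.

    For each mode the tube radius is set per gap from that mode's widest
    radial extent (DeltaR measured from the widest surface, which in the
    wrapped mode includes the wound filament).  Speeds are normalized by the
    free-space *unwrapped* swimming speed U0 and |Omega| by its free-space
    unwrapped value, as in the confinement figure.  Failed solves are
    recorded per-row and the sweep continues.
    """
    drive = drive or MotorDrive()
    gaps = sorted(set(float(x) for x in gaps), reverse=True)

    def omega_flag(sol):
        # lab-frame rotation rate of the flagellum (body rotation plus the
        # imposed relative motor rate)
        return float(sol.Omega[2] + drive.signed_rate)

    free = {}
    for mode, cfg in (("unwrapped", config_unwrapped),
                      ("wrapped", config_wrapped)):
        free[mode] = solve_swimming(cfg, FluidEnvironment(viscosity, None),
                                    drive, resolution)
    U0 = abs(free["unwrapped"].speed)
    Om0 = abs(free["unwrapped"].Omega[2])
    rows = []
    for mode, cfg in (("unwrapped", config_unwrapped),
                      ("wrapped", config_wrapped)):
        H = cfg.body.length
        extent = max_radial_extent(cfg)
        Omf0 = omega_flag(free["unwrapped"])
        rows.append({
            "gap": math.inf, "mode": mode, "tube_radius_um": math.inf,
            "U_um_per_s": free[mode].speed,
            "U_over_U0": free[mode].speed / U0,
            "Omega_over_Omega0": free[mode].Omega[2] / Om0,
            "Omega_flag_over_Omega_flag0": omega_flag(free[mode]) / Omf0,
            "motor_torque_pN_um": free[mode].motor_torque, "error": "",
        })
        for gap in gaps:
            R = extent + gap * H / 2
            try:
                tube = TubeGeometry(R, truncation_length, H)
                sol = solve_swimming(cfg, FluidEnvironment(viscosity, tube),
                                     drive, resolution)
                rows.append({
                    "gap": gap, "mode": mode, "tube_radius_um": R,
                    "U_um_per_s": sol.speed, "U_over_U0": sol.speed / U0,
                    "Omega_over_Omega0": sol.Omega[2] / Om0,
                    "Omega_flag_over_Omega_flag0": omega_flag(sol) / Omf0,
                    "motor_torque_pN_um": sol.motor_torque, "error": "",
                })
            except Exception as exc:  # record and continue
                rows.append({
                    "gap": gap, "mode": mode, "tube_radius_um": R,
                    "U_um_per_s": math.nan, "U_over_U0": math.nan,
                    "Omega_over_Omega0": math.nan,
                    "Omega_flag_over_Omega_flag0": math.nan,
                    "motor_torque_pN_um": math.nan, "error": str(exc),
                })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# flow field evaluation
# --------------------------------------------------------------------------

@dataclass
class FlowField:
    """Velocity field sampled on a grid of points outside all surfaces."""

    points: np.ndarray
    velocity: np.ndarray
    axial_over_U: np.ndarray
    mask: np.ndarray  # True where evaluated (outside surfaces)


def compute_flow_field(solution: MobilitySolution, grid_points: np.ndarray,
                       exclusion_radius: float = 0.06) -> FlowField:
    """Evaluate the boundary-integral velocity at grid points.

    Points inside the cell body, beyond the tube wall, or closer than
    ``exclusion_radius`` to any collocation point are masked (inside or on
    a surface), not evaluated.
    """
    gp = np.atleast_2d(np.asarray(grid_points, float))
    d2 = ((gp[:, None, :] - solution.points[None, :, :]) ** 2).sum(axis=2)
    mask = d2.min(axis=1) > exclusion_radius**2
    if solution.config is not None:
        mask &= solution.config.body.surface_distance(gp) > exclusion_radius
    if solution.tube is not None:
        rho = np.hypot(gp[:, 0], gp[:, 1])
        mask &= rho < solution.tube.radius - exclusion_radius
    vel = np.full_like(gp, np.nan)
    if mask.any():
        eps_t = np.full(int(mask.sum()), float(solution.eps.mean()))
        Mv = _stokeslet_blocks(gp[mask], solution.points, eps_t,
                               solution.eps, solution.viscosity)
        vel[mask] = (Mv @ solution.forces.ravel()).reshape(-1, 3)
    Uax = abs(solution.speed) if abs(solution.speed) > 0 else 1.0
    return FlowField(points=gp, velocity=vel,
                     axial_over_U=vel[:, 2] / Uax, mask=mask)
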