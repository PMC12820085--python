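"""Motor-driven elastic filament wrapping around a rigid cell body.

Discrete elastic rod (Kirchhoff) model of the flagellar filament: nodes plus
per-edge material-frame twist angles, with stretching (penalty), bending and
twisting elasticity under full geometric nonlinearity; curvature is the
discrete curvature binormal, twist is measured against time-parallel
reference frames.  The first edge is clamped at the attachment pole of a
fixed capsule body and the motor imposes its rotation as a twist boundary
condition (CW sense for wrapping).  The hook is the proximal joint, with
bending stiffness rescaled so a single joint reproduces the compliance of a
60 nm flexible element.  Hydrodynamics is local anisotropic drag (resistive
force theory); filament-body contact is a short-range attractive
2-4 (Lennard-Jones-like) well with a capped repulsive core.

Everything is nondimensional: lengths by the filament contour length L,
time by xi_perp L^4 / A, energies by A / L.  The physical inputs are the
stiffness ratios A_hook/A and C/A, the scaled motor rate, and the scaled
body/helix geometry.

Intrinsic shape: the filament's rest configuration is the coiled
polymorphic form (the form adopted during wrapping) attached through the
hook; the rest-state curvature/twist are extracted from the constructed
intrinsic centerline so that the initial elastic energy is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import CellBody, HelixShape, HELIX_PRESETS

__all__ = [
    "RodParams",
    "BodyInteraction",
    "RodState",
    "WrapOutcome",
    "init_rod",
    "step_rod",
    "simulate_wrapping",
    "classify_outcome",
    "phase_scan",
    "elastic_energy",
    "rod_forces",
    "DEFAULT_CONTOUR_UM",
]

#: Contour length (um) used to nondimensionalize the default geometry:
#: the coiled-form filament preset.
DEFAULT_CONTOUR_UM = HELIX_PRESETS["coiled"].contour_length


@dataclass(frozen=True)
class RodParams:
    """Nondimensional rod parameters (lengths in units of contour length L,
    time in units of xi_perp L^4 / A, stiffness in units of A)."""

    n_segments: int = 36
    bend_stiffness: float = 1.0           # A (nondimensional unit)
    twist_ratio: float = 0.75             # C/A
    hook_ratio: float = 0.02              # A_hook/A
    hook_length: float = 0.06 / DEFAULT_CONTOUR_UM   # 60 nm
    stretch_stiffness: float = 1000.0     # penalty scale (force/strain)
    drag_perp: float = 1.0                # xi_perp (unit)
    drag_par: float = 0.5                 # xi_par; xi_perp/xi_par = 2
    drag_rot: float = 0.0                 # per-length rotational drag;
                                          # 0 = quasi-static twist (the
                                          # physical limit: rotational drag
                                          # of a 20 nm filament is tiny)
    # intrinsic (rest) helix: the coiled polymorphic form by default
    helix_pitch: float = 1.0 / DEFAULT_CONTOUR_UM
    helix_radius: float = 0.5 / DEFAULT_CONTOUR_UM
    handedness: str = "left"
    # body geometry, scaled by the same L
    body_length: float = 2.5 / DEFAULT_CONTOUR_UM
    body_radius: float = 0.40 / DEFAULT_CONTOUR_UM

    def __post_init__(self) -> None:
        if self.n_segments < 8:
            raise ValueError("need at least 8 segments")
        for name in ("bend_stiffness", "twist_ratio", "hook_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        ratio = self.drag_perp / self.drag_par
        if not 1.5 <= ratio <= 2.0:
            raise ValueError("xi_perp/xi_par must lie in [1.5, 2]")

    @property
    def segment_length(self) -> float:
        return 1.0 / self.n_segments


@dataclass(frozen=True)
class BodyInteraction:
    """Filament-body contact: short-range attractive well (depth
    ``epsilon``, equilibrium clearance ``clearance``) with 6-12 shape,
    truncated at ``cutoff_factor * clearance`` and force-capped below
    ``cap_factor * clearance`` for numerical robustness."""

    epsilon: float = 0.35                 # well depth per node, units A/L
    clearance: float = 0.05 / DEFAULT_CONTOUR_UM
    cutoff_factor: float = 2.5
    cap_factor: float = 0.75
    repulsion_only: bool = False

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.clearance <= 0:
            raise ValueError("epsilon >= 0 and clearance > 0 required")


@dataclass
class RodState:
    """Filament state: node positions, per-edge twist angles, and the
    time-parallel reference frames."""

    x: np.ndarray           # (n+1, 3)
    theta: np.ndarray       # (n,)
    a1: np.ndarray          # (n, 3) reference directors
    tangents: np.ndarray    # (n, 3)
    time: float = 0.0
    rest: dict = field(default_factory=dict, repr=False)

    def copy(self) -> "RodState":
        return RodState(self.x.copy(), self.theta.copy(), self.a1.copy(),
                        self.tangents.copy(), self.time, self.rest)


@dataclass
class WrapOutcome:
    """Terminal morphology classification with its quantitative metrics.

    ``wrap_number`` is the signed winding of the filament about the body
    axis over the body length; ``proximal_fraction`` the fraction of
    filament nodes within the proximal zone (0.5 um of the attachment
    pole); ``contact_coverage`` the fraction of the body length with
    filament in the contact band.  Thresholds are recorded in
    ``criteria`` (they are artifact definitions, not measurements).
    """

    label: str
    wrap_number: float
    proximal_fraction: float
    contact_coverage: float
    time_to_steady: float
    steady: bool
    criteria: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _transport(v, t_old, t_new):
    """Parallel transport v from tangent t_old to t_new (Rodrigues)."""
    bx = t_old[1] * t_new[2] - t_old[2] * t_new[1]
    by = t_old[2] * t_new[0] - t_old[0] * t_new[2]
    bz = t_old[0] * t_new[1] - t_old[1] * t_new[0]
    s2 = bx * bx + by * by + bz * bz
    c = t_old[0] * t_new[0] + t_old[1] * t_new[1] + t_old[2] * t_new[2]
    out = np.empty(3)
    if s2 < 1e-24:
        out[0], out[1], out[2] = v[0], v[1], v[2]
        return out
    s = math.sqrt(s2)
    ax, ay, az = bx / s, by / s, bz / s
    dot_av = ax * v[0] + ay * v[1] + az * v[2]
    cx = ay * v[2] - az * v[1]
    cy = az * v[0] - ax * v[2]
    cz = ax * v[1] - ay * v[0]
    out[0] = v[0] * c + cx * s + ax * dot_av * (1 - c)
    out[1] = v[1] * c + cy * s + ay * dot_av * (1 - c)
    out[2] = v[2] * c + cz * s + az * dot_av * (1 - c)
    return out


@njit(cache=True, fastmath=True)
def _forces_kernel(x, theta, a1, lbar, vor, Bj, Cj, kb1r, kb2r, mbr,
                   ks, F, Gt, Hd, Ho, e, el, t, m1, m2):
    """Elastic forces on nodes (F) and twist-angle gradients (Gt = dE/dtheta).

    Returns the total elastic energy.  a1 must be current (transported);
    a2 = t x a1 is formed internally.
    """
    n = len(theta)
    F[:] = 0.0
    Gt[:] = 0.0
    Hd[:] = 0.0
    Ho[:] = 0.0
    energy = 0.0
    for j in range(n):
        for k in range(3):
            e[j, k] = x[j + 1, k] - x[j, k]
        el[j] = math.sqrt(e[j, 0]**2 + e[j, 1]**2 + e[j, 2]**2)
        for k in range(3):
            t[j, k] = e[j, k] / el[j]
        # a2 = t x a1
        a2x = t[j, 1] * a1[j, 2] - t[j, 2] * a1[j, 1]
        a2y = t[j, 2] * a1[j, 0] - t[j, 0] * a1[j, 2]
        a2z = t[j, 0] * a1[j, 1] - t[j, 1] * a1[j, 0]
        ct, st = math.cos(theta[j]), math.sin(theta[j])
        m1[j, 0] = ct * a1[j, 0] + st * a2x
        m1[j, 1] = ct * a1[j, 1] + st * a2y
        m1[j, 2] = ct * a1[j, 2] + st * a2z
        m2[j, 0] = -st * a1[j, 0] + ct * a2x
        m2[j, 1] = -st * a1[j, 1] + ct * a2y
        m2[j, 2] = -st * a1[j, 2] + ct * a2z
        # stretching
        eps_s = el[j] / lbar[j] - 1.0
        energy += 0.5 * ks * lbar[j] * eps_s * eps_s
        coef = ks * eps_s
        for k in range(3):
            F[j, k] += coef * t[j, k]
            F[j + 1, k] -= coef * t[j, k]
    for i in range(1, n):
        te = t[i - 1]
        tf = t[i]
        chi = 1.0 + te[0] * tf[0] + te[1] * tf[1] + te[2] * tf[2]
        if chi < 1e-12:
            chi = 1e-12
        kbx = 2.0 * (te[1] * tf[2] - te[2] * tf[1]) / chi
        kby = 2.0 * (te[2] * tf[0] - te[0] * tf[2]) / chi
        kbz = 2.0 * (te[0] * tf[1] - te[1] * tf[0]) / chi
        m1e, m2e = m1[i - 1], m2[i - 1]
        m1f, m2f = m1[i], m2[i]
        k1 = 0.5 * (kbx * (m2e[0] + m2f[0]) + kby * (m2e[1] + m2f[1])
                    + kbz * (m2e[2] + m2f[2]))
        k2 = -0.5 * (kbx * (m1e[0] + m1f[0]) + kby * (m1e[1] + m1f[1])
                     + kbz * (m1e[2] + m1f[2]))
        dk1 = k1 - kb1r[i - 1]
        dk2 = k2 - kb2r[i - 1]
        B = Bj[i - 1]
        energy += 0.5 * B * (dk1 * dk1 + dk2 * dk2) / vor[i - 1]
        g1 = B * dk1 / vor[i - 1]
        g2 = B * dk2 / vor[i - 1]
        # gradients of curvatures wrt edges (scalar-inlined)
        tt0 = (te[0] + tf[0]) / chi
        tt1 = (te[1] + tf[1]) / chi
        tt2 = (te[2] + tf[2]) / chi
        tm10 = (m1e[0] + m1f[0]) / chi
        tm11 = (m1e[1] + m1f[1]) / chi
        tm12 = (m1e[2] + m1f[2]) / chi
        tm20 = (m2e[0] + m2f[0]) / chi
        tm21 = (m2e[1] + m2f[1]) / chi
        tm22 = (m2e[2] + m2f[2]) / chi
        fXm2_0 = tf[1] * tm22 - tf[2] * tm21
        fXm2_1 = tf[2] * tm20 - tf[0] * tm22
        fXm2_2 = tf[0] * tm21 - tf[1] * tm20
        eXm2_0 = te[1] * tm22 - te[2] * tm21
        eXm2_1 = te[2] * tm20 - te[0] * tm22
        eXm2_2 = te[0] * tm21 - te[1] * tm20
        fXm1_0 = tf[1] * tm12 - tf[2] * tm11
        fXm1_1 = tf[2] * tm10 - tf[0] * tm12
        fXm1_2 = tf[0] * tm11 - tf[1] * tm10
        eXm1_0 = te[1] * tm12 - te[2] * tm11
        eXm1_1 = te[2] * tm10 - te[0] * tm12
        eXm1_2 = te[0] * tm11 - te[1] * tm10
        ile = 1.0 / el[i - 1]
        ilf = 1.0 / el[i]
        ge0 = (g1 * (-k1 * tt0 + fXm2_0) + g2 * (-k2 * tt0 - fXm1_0)) * ile
        ge1 = (g1 * (-k1 * tt1 + fXm2_1) + g2 * (-k2 * tt1 - fXm1_1)) * ile
        ge2 = (g1 * (-k1 * tt2 + fXm2_2) + g2 * (-k2 * tt2 - fXm1_2)) * ile
        gf0 = (g1 * (-k1 * tt0 - eXm2_0) + g2 * (-k2 * tt0 + eXm1_0)) * ilf
        gf1 = (g1 * (-k1 * tt1 - eXm2_1) + g2 * (-k2 * tt1 + eXm1_1)) * ilf
        gf2 = (g1 * (-k1 * tt2 - eXm2_2) + g2 * (-k2 * tt2 + eXm1_2)) * ilf
        F[i - 1, 0] += ge0
        F[i - 1, 1] += ge1
        F[i - 1, 2] += ge2
        F[i, 0] += gf0 - ge0
        F[i, 1] += gf1 - ge1
        F[i, 2] += gf2 - ge2
        F[i + 1, 0] -= gf0
        F[i + 1, 1] -= gf1
        F[i + 1, 2] -= gf2
        # material-frame rotation part of the bending gradient
        kb_m1e = kbx * m1e[0] + kby * m1e[1] + kbz * m1e[2]
        kb_m2e = kbx * m2e[0] + kby * m2e[1] + kbz * m2e[2]
        kb_m1f = kbx * m1f[0] + kby * m1f[1] + kbz * m1f[2]
        kb_m2f = kbx * m2f[0] + kby * m2f[1] + kbz * m2f[2]
        Gt[i - 1] += g1 * (-0.5 * kb_m1e) + g2 * (-0.5 * kb_m2e)
        Gt[i] += g1 * (-0.5 * kb_m1f) + g2 * (-0.5 * kb_m2f)
        # Gauss-Newton theta-Hessian of the bending energy (for the
        # quasi-static twist solve)
        ue, ve = -0.5 * kb_m1e, -0.5 * kb_m2e
        uf, vf = -0.5 * kb_m1f, -0.5 * kb_m2f
        BoV = B / vor[i - 1]
        Hd[i - 1] += BoV * (ue * ue + ve * ve)
        Hd[i] += BoV * (uf * uf + vf * vf)
        Ho[i - 1] += BoV * (ue * uf + ve * vf)
    # note: twist energy handled outside (needs reference twist)
    return energy


@njit(cache=True, fastmath=True)
def _ref_twist(a1, t, rt):
    """Reference twist per interior joint from the time-parallel frames
    (written into ``rt``)."""
    n = len(t)
    rt[0] = 0.0
    for i in range(1, n):
        # transport a1[i-1] from t[i-1] to t[i] (inline Rodrigues)
        px, py, pz = t[i - 1, 0], t[i - 1, 1], t[i - 1, 2]
        qx, qy, qz = t[i, 0], t[i, 1], t[i, 2]
        bx = py * qz - pz * qy
        by = pz * qx - px * qz
        bz = px * qy - py * qx
        s2 = bx * bx + by * by + bz * bz
        vx, vy, vz = a1[i - 1, 0], a1[i - 1, 1], a1[i - 1, 2]
        if s2 >= 1e-24:
            cth = px * qx + py * qy + pz * qz
            sth = math.sqrt(s2)
            ax, ay, az = bx / sth, by / sth, bz / sth
            dav = ax * vx + ay * vy + az * vz
            cxx = ay * vz - az * vy
            cyy = az * vx - ax * vz
            czz = ax * vy - ay * vx
            vx, vy, vz = (vx * cth + cxx * sth + ax * dav * (1 - cth),
                          vy * cth + cyy * sth + ay * dav * (1 - cth),
                          vz * cth + czz * sth + az * dav * (1 - cth))
        # signed angle from transported vector to a1[i] around t[i]
        cx = vy * a1[i, 2] - vz * a1[i, 1]
        cy = vz * a1[i, 0] - vx * a1[i, 2]
        cz = vx * a1[i, 1] - vy * a1[i, 0]
        s = cx * qx + cy * qy + cz * qz
        c = vx * a1[i, 0] + vy * a1[i, 1] + vz * a1[i, 2]
        rt[i] = math.atan2(s, c)


@njit(cache=True, fastmath=True)
def _twist_terms(x, theta, a1, t, el, Cj, vor, mbr, F, Gt, rt):
    """Add twisting-energy gradients (including the holonomy force)."""
    n = len(theta)
    _ref_twist(a1, t, rt)
    energy = 0.0
    for i in range(1, n):
        tw = theta[i] - theta[i - 1] + rt[i]
        dtw = tw - mbr[i - 1]
        C = Cj[i - 1]
        energy += 0.5 * C * dtw * dtw / vor[i - 1]
        g = C * dtw / vor[i - 1]
        Gt[i] += g
        Gt[i - 1] -= g
        te = t[i - 1]
        tf = t[i]
        chi = 1.0 + te[0] * tf[0] + te[1] * tf[1] + te[2] * tf[2]
        if chi < 1e-12:
            chi = 1e-12
        kbx = 2.0 * (te[1] * tf[2] - te[2] * tf[1]) / chi
        kby = 2.0 * (te[2] * tf[0] - te[0] * tf[2]) / chi
        kbz = 2.0 * (te[0] * tf[1] - te[1] * tf[0]) / chi
        hle = 0.5 * g / el[i - 1]
        hlf = 0.5 * g / el[i]
        # map to nodes: e_{i-1}=x_i-x_{i-1}, e_i=x_{i+1}-x_i
        F[i - 1, 0] += hle * kbx
        F[i - 1, 1] += hle * kby
        F[i - 1, 2] += hle * kbz
        F[i, 0] += (hlf - hle) * kbx
        F[i, 1] += (hlf - hle) * kby
        F[i, 2] += (hlf - hle) * kbz
        F[i + 1, 0] -= hlf * kbx
        F[i + 1, 1] -= hlf * kby
        F[i + 1, 2] -= hlf * kbz
    return energy


@njit(cache=True, fastmath=True)
def _body_force(x, F, body_a, body_zc, eps, h0, cutoff, hcap, n_clamp):
    """Capsule contact: 6-12 well of depth eps at clearance h0, truncated
    at ``cutoff`` and force-capped below ``hcap``."""
    energy = 0.0
    npts = len(x)
    # shift so the potential is continuous at the cutoff
    sc = h0 / cutoff
    ushift = eps * ((sc * sc) ** 2 - 2.0 * sc * sc)
    for i in range(n_clamp, npts):
        zc = x[i, 2]
        if zc > body_zc:
            zc = body_zc
        elif zc < -body_zc:
            zc = -body_zc
        dx, dy, dz = x[i, 0], x[i, 1], x[i, 2] - zc
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-12:
            continue
        h = d - body_a
        if h >= cutoff:
            continue
        hh = h if h > hcap else hcap
        s2 = (h0 / hh) ** 2
        # soft 2-4 well: U(h) = eps (s^4 - 2 s^2); f_h = -dU/dh
        fh = 4.0 * eps / hh * (s2 * s2 - s2)
        if h > hcap:
            energy += eps * (s2 * s2 - 2.0 * s2) - ushift
        else:
            s2c = (h0 / hcap) ** 2
            energy += (eps * (s2c * s2c - 2.0 * s2c) - ushift
                       + 4.0 * eps / hcap * (s2c * s2c - s2c) * (hcap - h))
        nx, ny, nz = dx / d, dy / d, dz / d
        F[i, 0] += fh * nx
        F[i, 1] += fh * ny
        F[i, 2] += fh * nz
    return energy


@njit(cache=True, fastmath=True)
def _run_kernel(x, theta, a1, tprev, lbar, vor, Bj, Cj, kb1r, kb2r, mbr,
                ks, xi_par, xi_perp, zeta_rot,
                body_a, body_zc, eps, h0, cutoff, hcap,
                omega, t0, dt, nsteps, n_clamp):
    """Advance the overdamped rod ``nsteps`` steps; returns (t, ok)."""
    n = len(theta)
    npts = len(x)
    F = np.zeros((npts, 3))
    Gt = np.zeros(n)
    Hd = np.zeros(n)
    Ho = np.zeros(n)
    e = np.empty((n, 3))
    el = np.empty(n)
    t = np.empty((n, 3))
    m1 = np.empty((n, 3))
    m2 = np.empty((n, 3))
    rt = np.empty(n)
    m = n - 1
    diag = np.empty(m)
    lower = np.empty(m)
    upper = np.empty(m)
    rhs = np.empty(m)
    delta = np.empty(m)
    theta0_base = theta[0]   # motor angle continues from its current value
    tcur = t0
    for step in range(nsteps):
        # transport reference frames to current tangents (inline Rodrigues)
        for j in range(n):
            tjx = x[j + 1, 0] - x[j, 0]
            tjy = x[j + 1, 1] - x[j, 1]
            tjz = x[j + 1, 2] - x[j, 2]
            norm = math.sqrt(tjx * tjx + tjy * tjy + tjz * tjz)
            tjx, tjy, tjz = tjx / norm, tjy / norm, tjz / norm
            px, py, pz = tprev[j, 0], tprev[j, 1], tprev[j, 2]
            bx = py * tjz - pz * tjy
            by = pz * tjx - px * tjz
            bz = px * tjy - py * tjx
            s2 = bx * bx + by * by + bz * bz
            vx, vy, vz = a1[j, 0], a1[j, 1], a1[j, 2]
            if s2 >= 1e-24:
                c = px * tjx + py * tjy + pz * tjz
                s = math.sqrt(s2)
                ax, ay, az = bx / s, by / s, bz / s
                dav = ax * vx + ay * vy + az * vz
                cxx = ay * vz - az * vy
                cyy = az * vx - ax * vz
                czz = ax * vy - ay * vx
                vx2 = vx * c + cxx * s + ax * dav * (1 - c)
                vy2 = vy * c + cyy * s + ay * dav * (1 - c)
                vz2 = vz * c + czz * s + az * dav * (1 - c)
                vx, vy, vz = vx2, vy2, vz2
            dot = vx * tjx + vy * tjy + vz * tjz
            vx -= dot * tjx
            vy -= dot * tjy
            vz -= dot * tjz
            nn = math.sqrt(vx * vx + vy * vy + vz * vz)
            a1[j, 0], a1[j, 1], a1[j, 2] = vx / nn, vy / nn, vz / nn
            tprev[j, 0], tprev[j, 1], tprev[j, 2] = tjx, tjy, tjz
        _forces_kernel(x, theta, a1, lbar, vor, Bj, Cj,
                       kb1r, kb2r, mbr, ks, F, Gt, Hd, Ho, e, el, t, m1, m2)
        _twist_terms(x, theta, a1, t, el, Cj, vor, mbr, F, Gt, rt)
        _body_force(x, F, body_a, body_zc, eps, h0, cutoff, hcap, n_clamp)
        # overdamped update; clamped nodes and driven edge excluded
        for i in range(n_clamp, npts):
            # local tangent at node: average of adjacent edges
            j0 = i - 1 if i - 1 >= 0 else 0
            j1 = i if i < n else n - 1
            tx = 0.5 * (t[j0, 0] + t[j1, 0])
            ty = 0.5 * (t[j0, 1] + t[j1, 1])
            tz = 0.5 * (t[j0, 2] + t[j1, 2])
            tn = math.sqrt(tx * tx + ty * ty + tz * tz)
            if tn > 1e-12:
                tx, ty, tz = tx / tn, ty / tn, tz / tn
            ln = 0.5 * (lbar[j0] + lbar[j1]) if 0 < i < npts - 1 \
                else 0.5 * lbar[j0 if i > 0 else 0]
            ft = F[i, 0] * tx + F[i, 1] * ty + F[i, 2] * tz
            mpar = 1.0 / (xi_par * ln)
            mperp = 1.0 / (xi_perp * ln)
            x[i, 0] += dt * (mperp * F[i, 0] + (mpar - mperp) * ft * tx)
            x[i, 1] += dt * (mperp * F[i, 1] + (mpar - mperp) * ft * ty)
            x[i, 2] += dt * (mperp * F[i, 2] + (mpar - mperp) * ft * tz)
            if not math.isfinite(x[i, 0]):
                return tcur, False
        tcur += dt
        theta[0] = theta0_base + omega * (tcur - t0)
        if zeta_rot > 0.0:
            # overdamped twist dynamics
            for j in range(1, n):
                theta[j] -= dt * Gt[j] / (zeta_rot * lbar[j])
                if not math.isfinite(theta[j]):
                    return tcur, False
        else:
            # quasi-static twist: one Newton step on the twist-energy
            # Hessian (tridiagonal; the bending-theta coupling is weak and
            # handled by the next step's gradient)
            if m > 0:
                for j in range(1, n):
                    d = Cj[j - 1] / vor[j - 1]
                    diag[j - 1] = d + Hd[j]
                    if j + 1 <= n - 1:
                        diag[j - 1] += Cj[j] / vor[j]
                        upper[j - 1] = -Cj[j] / vor[j] + Ho[j]
                    else:
                        upper[j - 1] = 0.0
                    lower[j - 1] = -d + Ho[j - 1]
                    rhs[j - 1] = -Gt[j]
                # Thomas algorithm (lower[k] couples unknown k to k-1)
                for k in range(1, m):
                    w = lower[k] / diag[k - 1]
                    diag[k] -= w * upper[k - 1]
                    rhs[k] -= w * rhs[k - 1]
                delta[m - 1] = rhs[m - 1] / diag[m - 1]
                for k in range(m - 2, -1, -1):
                    delta[k] = (rhs[k] - upper[k] * delta[k + 1]) / diag[k]
                # trust region: the bending energy is trigonometric in
                # theta, so keep Newton inside its quadratic basin
                dmax = 0.0
                for k in range(m):
                    a = abs(delta[k])
                    if a > dmax:
                        dmax = a
                scale = 1.0 if dmax <= 0.3 else 0.3 / dmax
                for k in range(m):
                    theta[k + 1] += scale * delta[k]
            for j in range(1, n):
                if not math.isfinite(theta[j]):
                    return tcur, False
    return tcur, True


# --------------------------------------------------------------------------
# python-level API
# --------------------------------------------------------------------------

def _intrinsic_centerline(params: RodParams) -> np.ndarray:
    """Initial/rest centerline: straight hook edge emerging axially from
    the attachment pole, then the intrinsic helix coaxial with the body
    axis, extending away from the body."""
    n = params.n_segments
    ds = params.segment_length
    zp = params.body_length / 2
    R, p = params.helix_radius, params.helix_pitch
    sgn = -1.0 if params.handedness == "left" else 1.0
    b = p / (2 * math.pi)
    pts = np.empty((n + 1, 3))
    pts[0] = (0.0, 0.0, zp)
    pts[1] = (0.0, 0.0, zp + ds)
    # helix: arc-length parametrized, starting at node 1
    c = math.sqrt(R * R + b * b)
    phi = np.arange(1, n) * ds / c   # nodes 2..n, arc measured from node 1
    hel = np.column_stack([R * (np.cos(phi) - 1.0),
                           sgn * R * np.sin(phi),
                           b * phi])
    # rotate the helix so its starting tangent continues the straight hook
    # (tangent = +z): the hook is then straight in the rest state and the
    # initial elastic energy is exactly zero.
    t0 = np.array([0.0, sgn * R, b]) / c
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(t0, zhat)
    s_, c_ = np.linalg.norm(v), float(t0 @ zhat)
    if s_ > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                       [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c_) / s_**2)
        hel = hel @ rot.T
    pts[2:] = pts[1] + hel
    return pts


def _rest_arrays(params: RodParams, x0: np.ndarray, a1: np.ndarray,
                 theta: np.ndarray) -> dict:
    """Rest-state arrays; intrinsic curvature/twist extracted from the
    intrinsic centerline so the built state has zero elastic energy."""
    n = params.n_segments
    e = np.diff(x0, axis=0)
    el = np.linalg.norm(e, axis=1)
    t = e / el[:, None]
    lbar = el.copy()
    vor = 0.5 * (lbar[:-1] + lbar[1:])
    # stiffness per joint; the hook joint(s) cover hook_length from the clamp
    Bj = np.full(n - 1, params.bend_stiffness)
    Cj = np.full(n - 1, params.twist_ratio * params.bend_stiffness)
    arc = np.cumsum(lbar)[:-1]      # arc position of joint i = after edge i-1
    hook_joints = np.where(arc - lbar[0] < params.hook_length + 1e-12)[0]
    if len(hook_joints) == 0:
        hook_joints = np.array([0])
    # one discrete joint standing in for a flexible element of length
    # hook_length: B_joint = A_hook * l_joint / hook_length
    for j in hook_joints:
        Bj[j] = (params.hook_ratio * params.bend_stiffness
                 * vor[j] / params.hook_length * len(hook_joints))
    # intrinsic curvature/twist from the built state
    m1 = np.cos(theta)[:, None] * a1 + np.sin(theta)[:, None] * \
        np.cross(t, a1)
    m2 = -np.sin(theta)[:, None] * a1 + np.cos(theta)[:, None] * \
        np.cross(t, a1)
    kb1r = np.empty(n - 1)
    kb2r = np.empty(n - 1)
    for i in range(1, n):
        chi = 1.0 + float(t[i - 1] @ t[i])
        kb = 2.0 * np.cross(t[i - 1], t[i]) / chi
        kb1r[i - 1] = 0.5 * float(kb @ (m2[i - 1] + m2[i]))
        kb2r[i - 1] = -0.5 * float(kb @ (m1[i - 1] + m1[i]))
    rt = np.empty(n)
    _ref_twist(np.ascontiguousarray(a1), np.ascontiguousarray(t), rt)
    mbr = np.array([theta[i] - theta[i - 1] + rt[i] for i in range(1, n)])
    # note: the hook joint keeps the (near-zero) discrete curvature of the
    # built centerline, so the rest state has exactly zero energy
    return {"lbar": lbar, "vor": vor, "Bj": Bj, "Cj": Cj,
            "kb1r": kb1r, "kb2r": kb2r, "mbr": mbr,
            "hook_joints": hook_joints}


def init_rod(params: RodParams, body: CellBody | None = None,
             seed: int = 0, perturbation: float = 1e-3) -> RodState:
    """Build the initial rod state at mechanical rest (intrinsic shape),
    with an optional small seeded transverse perturbation on free nodes.

    The state is bit-reproducible for a fixed seed.  Raises if the
    intrinsic centerline penetrates the body.
    """
    x = _intrinsic_centerline(params)
    # frames: a1 transported along the curve from an arbitrary start
    e = np.diff(x, axis=0)
    t = e / np.linalg.norm(e, axis=1)[:, None]
    a1 = np.empty_like(t)
    ref = np.array([1.0, 0.0, 0.0])
    a1[0] = ref - (ref @ t[0]) * t[0]
    a1[0] /= np.linalg.norm(a1[0])
    for j in range(1, len(t)):
        v = _transport(np.ascontiguousarray(a1[j - 1]),
                       np.ascontiguousarray(t[j - 1]),
                       np.ascontiguousarray(t[j]))
        v -= (v @ t[j]) * t[j]
        a1[j] = v / np.linalg.norm(v)
    theta = np.zeros(len(t))
    rest = _rest_arrays(params, x, a1, theta)
    # body-penetration check on the rest shape
    zc = max(params.body_length / 2 - params.body_radius, 0.0)
    zcl = np.clip(x[:, 2], -zc, zc)
    d = np.sqrt(x[:, 0]**2 + x[:, 1]**2 + (x[:, 2] - zcl)**2)
    if np.any(d[2:] < params.body_radius):
        raise ValueError("initial filament penetrates the body")
    if perturbation > 0:
        rng = np.random.default_rng(seed)
        x[2:] += perturbation * rng.standard_normal((len(x) - 2, 3))
    return RodState(x=x, theta=theta, a1=a1, tangents=t.copy(), rest=rest)


def _kernel_args(state: RodState, params: RodParams,
                 interaction: BodyInteraction):
    r = state.rest
    zc = max(params.body_length / 2 - params.body_radius, 0.0)
    h0 = interaction.clearance
    # repulsion-only: truncate the well at its minimum (purely repulsive)
    cutoff = h0 if interaction.repulsion_only else \
        interaction.cutoff_factor * h0
    return (r["lbar"], r["vor"], r["Bj"], r["Cj"], r["kb1r"], r["kb2r"],
            r["mbr"], params.stretch_stiffness, params.drag_par,
            params.drag_perp, params.drag_rot, params.body_radius, zc,
            interaction.epsilon, h0, cutoff, interaction.cap_factor * h0)


def stable_dt(params: RodParams, safety: float = 0.4,
              interaction: BodyInteraction | None = None) -> float:
    """Explicit-Euler stability estimate.

    Discrete mode rates with node mobility 1/(xi l): bending <= 16 B/(xi
    l^4), stretching <= 4 k_s/(xi_par l^2), contact from the capped-force
    slope of the 6-12 well.  With quasi-static twist (drag_rot = 0) the
    twist modes impose no constraint; with explicit twist they do.
    """
    el = params.segment_length
    rate_bend = 16.0 * params.bend_stiffness / (params.drag_perp * el**4)
    rate_stretch = 4.0 * params.stretch_stiffness / (params.drag_par * el**2)
    rates = [rate_bend, rate_stretch]
    if params.drag_rot > 0:
        rates.append(4.0 * params.twist_ratio * params.bend_stiffness
                     / (params.drag_rot * el**3))
    inter = interaction or BodyInteraction()
    if inter.epsilon > 0:
        h = inter.cap_factor * inter.clearance
        s2 = (inter.clearance / h) ** 2
        k_contact = inter.epsilon / h**2 * (20 * s2 * s2 - 12 * s2)
        rates.append(abs(k_contact) / (params.drag_perp * el))
    return safety * 2.0 / max(rates)


def step_rod(state: RodState, params: RodParams,
             interaction: BodyInteraction, motor_rate: float,
             dt: float, n_steps: int = 1) -> RodState:
    """Advance the rod by ``n_steps`` overdamped steps (in place on a copy).

    ``motor_rate`` is the signed scaled rotation rate imposed on the
    clamped proximal edge (negative = CW viewed from behind the pole).
    Raises on numerical blow-up, returning the diagnosis in the message.
    """
    if dt > stable_dt(params, 1.0, interaction):
        raise ValueError(f"dt={dt:g} above the stability bound "
                         f"{stable_dt(params, 1.0, interaction):g}")
    new = state.copy()
    args = _kernel_args(new, params, interaction)
    tcur, ok = _run_kernel(new.x, new.theta, new.a1, new.tangents, *args,
                           motor_rate, new.time, dt, n_steps, 2)
    new.time = tcur
    if not ok:
        raise FloatingPointError(
            f"rod integration diverged at t={tcur:.4g} (dt too large or "
            "contact too stiff); last valid state not retained")
    return new


def elastic_energy(state: RodState, params: RodParams) -> float:
    """Total elastic energy (stretch + bend + twist) of a state."""
    r = state.rest
    F = np.zeros_like(state.x)
    Gt = np.zeros_like(state.theta)
    # frames must be consistent with current tangents
    st = state.copy()
    _sync_frames(st)
    en, (e, el, t) = _forces_python(st, params, F, Gt)
    en += _twist_python(st, params, t, el, F, Gt)
    return float(en)


def rod_forces(state: RodState, params: RodParams):
    """Elastic forces and twist gradients for the current state (used by
    the finite-difference consistency tests)."""
    r = state.rest
    F = np.zeros_like(state.x)
    Gt = np.zeros_like(state.theta)
    st = state.copy()
    _sync_frames(st)
    _, (e, el, t) = _forces_python(st, params, F, Gt)
    _twist_python(st, params, t, el, F, Gt)
    return F, Gt


def _forces_python(st: "RodState", params: RodParams, F, Gt):
    """Thin wrapper allocating kernel workspaces (non-hot path)."""
    r = st.rest
    n = len(st.theta)
    Hd = np.zeros(n)
    Ho = np.zeros(n)
    e = np.empty((n, 3))
    el = np.empty(n)
    t = np.empty((n, 3))
    m1 = np.empty((n, 3))
    m2 = np.empty((n, 3))
    en = _forces_kernel(st.x, st.theta, st.a1, r["lbar"], r["vor"],
                        r["Bj"], r["Cj"], r["kb1r"], r["kb2r"], r["mbr"],
                        params.stretch_stiffness, F, Gt, Hd, Ho,
                        e, el, t, m1, m2)
    return en, (e, el, t)


def _twist_python(st: "RodState", params: RodParams, t, el, F, Gt):
    r = st.rest
    rt = np.empty(len(st.theta))
    return _twist_terms(st.x, st.theta, st.a1, t, el, r["Cj"], r["vor"],
                        r["mbr"], F, Gt, rt)


def _sync_frames(state: RodState) -> None:
    """Transport reference frames onto the current tangents."""
    e = np.diff(state.x, axis=0)
    t = e / np.linalg.norm(e, axis=1)[:, None]
    for j in range(len(t)):
        v = _transport(np.ascontiguousarray(state.a1[j]),
                       np.ascontiguousarray(state.tangents[j]),
                       np.ascontiguousarray(t[j]))
        v -= (v @ t[j]) * t[j]
        state.a1[j] = v / np.linalg.norm(v)
        state.tangents[j] = t[j]


# --------------------------------------------------------------------------
# wrapping simulation, classification, phase scan
# --------------------------------------------------------------------------

def classify_outcome(states, params: RodParams,
                     steady_threshold: float = 5e-3,
                     steady: bool | None = None) -> WrapOutcome:
    """Classify the terminal filament morphology.

    Operational thresholds (recorded in the outcome):
    wrapped   - |wrap_number| >= 1 and contact over >= half the body length;
    ring      - >= 60% of the filament within 0.5 um of the proximal pole
                without body-length contact coverage;
    incomplete- partial winding hugging the body near a pole without
                half-length coverage: |wrap_number| >= 0.5, or filament
                piled at the proximal end (>= 30% of nodes) while touching
                the body;
    other     - anything else (including a straight trailing filament or
                the unchanged free coil).

    ``states`` is a list of RodState snapshots; steadiness is judged from
    the last two unless ``steady`` is given explicitly.  Refuses to
    classify a visibly non-steady trajectory.
    """
    if isinstance(states, RodState):
        states = [states]
    if steady is None:
        if len(states) >= 2:
            d = np.max(np.linalg.norm(states[-1].x - states[-2].x, axis=1))
            steady = d < steady_threshold
        else:
            steady = True
    last = states[-1]
    L = 1.0  # contour length, nondimensional
    um = 1.0 / DEFAULT_CONTOUR_UM          # one micrometre, scaled
    H, a = params.body_length, params.body_radius
    x = last.x[2:]                          # exclude clamped nodes
    rho = np.hypot(x[:, 0], x[:, 1])
    phi = np.unwrap(np.arctan2(x[:, 1], x[:, 0]))
    z = x[:, 2]
    in_body = (z >= -H / 2) & (z <= H / 2)
    contact_band = a + 3.0 * (0.05 * um)    # within ~3 clearances of surface
    near = rho <= contact_band
    # signed winding about the axis over the body length (consecutive nodes
    # both alongside the body and near its surface)
    wrap_angle = 0.0
    for i in range(len(x) - 1):
        if in_body[i] and in_body[i + 1] and near[i] and near[i + 1]:
            wrap_angle += phi[i + 1] - phi[i]
    wrap_number = wrap_angle / (2 * math.pi)
    # contact coverage of the body length
    sel = in_body & near
    if sel.any():
        zs = np.sort(z[sel])
        width = min(zs[-1], H / 2) - max(zs[0], -H / 2)
        coverage = max(width, 0.0) / H
    else:
        coverage = 0.0
    # proximal zone: within 0.5 um of the attachment pole
    prox = np.linalg.norm(x - np.array([0.0, 0.0, H / 2]), axis=1) \
        < 0.5 * um + a
    proximal_fraction = float(prox.mean())
    criteria = {
        "wrap_number_min": 1.0, "coverage_min": 0.5,
        "proximal_fraction_min": 0.6, "partial_wrap_min": 0.5,
        "incomplete_proximal_min": 0.3, "incomplete_coverage_min": 0.1,
        "contact_band": float(contact_band),
        "proximal_zone_um": 0.5,
        "steady_threshold": steady_threshold,
    }
    if not steady:
        label = "other"
    elif abs(wrap_number) >= 1.0 and coverage >= 0.5:
        label = "wrapped"
    elif proximal_fraction >= 0.6 and coverage < 0.5:
        label = "ring"
    elif coverage < 0.5 and (abs(wrap_number) >= 0.5
                             or (proximal_fraction >= 0.3
                                 and coverage >= 0.1)):
        label = "incomplete"
    else:
        label = "other"
    return WrapOutcome(
        label=label, wrap_number=float(wrap_number),
        proximal_fraction=proximal_fraction,
        contact_coverage=float(coverage),
        time_to_steady=last.time, steady=bool(steady), criteria=criteria)


def simulate_wrapping(params: RodParams | None = None,
                      interaction: BodyInteraction | None = None,
                      motor_rate: float = -500.0,
                      duration: float = 0.5,
                      seed: int = 0,
                      dt: float | None = None,
                      check_interval: float = 0.02,
                      relax_time: float = 0.06,
                      capture_checks: int = 2):
    """Motor-driven wrapping simulation with arrest-and-relax protocol.

    The motor runs at ``motor_rate`` (scaled; negative = CW, the wrapping
    sense) until either the wrapped morphology is expressed - the
    wrap/coverage thresholds hold for ``capture_checks`` consecutive
    metric checks - or the ``duration`` cap is reached.  The motor is then
    arrested (clamp angle frozen) and the filament relaxes for
    ``relax_time`` before the arrested shape is classified.  With the body
    held fixed, the thrust of a wound rotating filament slowly screws it
    off the pole, so sustained-drive snapshots cycle; the arrested state
    is the reproducible observable (see the methods note).

    Returns (snapshots, WrapOutcome).
    """
    params = params or RodParams()
    interaction = interaction or BodyInteraction()
    if dt is None:
        dt = stable_dt(params, interaction=interaction)
    state = init_rod(params, seed=seed)
    snaps = [state.copy()]
    block = max(1, int(round(check_interval / dt)))
    hits = 0
    while state.time < duration:
        state = step_rod(state, params, interaction, motor_rate, dt, block)
        snaps.append(state.copy())
        o = classify_outcome([state], params, steady=True)
        if abs(o.wrap_number) >= 1.0 and o.contact_coverage >= 0.5:
            hits += 1
            if hits >= capture_checks:
                break
        else:
            hits = 0
    # motor arrest and relaxation to a steady shape
    state = step_rod(state, params, interaction, 0.0, dt,
                     max(1, int(round(relax_time / dt))))
    snaps.append(state.copy())
    probe = step_rod(state, params, interaction, 0.0, dt,
                     max(1, int(round(0.01 / dt))))
    still = float(np.max(np.linalg.norm(probe.x - state.x, axis=1)))
    outcome = classify_outcome([state], params, steady=still < 5e-3)
    return snaps, outcome


def phase_scan(hook_ratios, twist_ratios, seeds=(0,),
               params: RodParams | None = None,
               interaction: BodyInteraction | None = None,
               motor_rate: float = -500.0, duration: float = 0.5,
               dt: float | None = None):
    """Outcome table over a (A_hook/A, C/A) grid with replicate seeds.

    Per-cell failures are recorded (label ``failed``) and the scan
    continues.  Returns a tidy DataFrame.
    """
    import pandas as pd
    base = params or RodParams()
    rows = []
    for hr in hook_ratios:
        for cr in twist_ratios:
            for seed in seeds:
                p = replace(base, hook_ratio=float(hr),
                            twist_ratio=float(cr))
                try:
                    _, out = simulate_wrapping(p, interaction, motor_rate,
                                               duration, seed, dt)
                    rows.append({
                        "ahook_ratio": hr, "ca_ratio": cr, "seed": seed,
                        "label": out.label, "wrap_number": out.wrap_number,
                        "proximal_fraction": out.proximal_fraction,
                        "contact_coverage": out.contact_coverage,
                        "t_steady": out.time_to_steady,
                        "steady": out.steady, "error": "",
                    })
                except Exception as exc:
                    rows.append({
                        "ahook_ratio": hr, "ca_ratio": cr, "seed": seed,
                        "label": "failed", "wrap_number": math.nan,
                        "proximal_fraction": math.nan,
                        "contact_coverage": math.nan, "t_steady": math.nan,
                        "steady": False, "error": str(exc),
                    })
    return pd.DataFrame(rows)
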