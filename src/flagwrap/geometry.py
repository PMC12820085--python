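"""Swimmer and channel geometry.

Builds centerlines and triangulated surface meshes for the model bacterium —
a capsule-shaped cell body with a single helical flagellar filament in either
the *unwrapped* (trailing, normal-form helix) or *wrapped* (wound around the
body like a screw thread, coiled-form parameters) configuration — and for the
confining circular tube that stands in for a micrometer-scale passage.

Internal units are micrometres throughout.  The flagellar filament is meshed
as a slender tube swept along its centerline; panel areas of revolution
primitives are rescaled to the analytic surface area so that the meshes act
as accurate quadrature rules for the boundary-integral solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HelixShape",
    "CellBody",
    "TubeGeometry",
    "SwimmerConfiguration",
    "SurfaceMesh",
    "HELIX_PRESETS",
    "preset_config",
    "build_helix_centerline",
    "build_wrapped_centerline",
    "build_surface_meshes",
    "build_capsule_mesh",
    "build_sphere_mesh",
    "build_tube_wall_mesh",
    "sweep_tube_mesh",
    "capsule_area",
    "normalized_gap",
    "max_radial_extent",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixShape:
    """Helical filament shape parameters.

    Parameters
    ----------
    pitch : float
        Axial rise per turn, um.  Must be positive.
    radius : float
        Helix radius, um.  Zero degenerates to a straight filament.
    n_turns : float
        Number of turns (positive real).
    handedness : {"left", "right"}
        Chirality of the helix.  Biological normal-form flagella are
        left-handed.
    taper_fraction : float
        Fraction of the contour length over which the helix radius grows
        linearly from zero at the attachment point; avoids a singular
        attachment.  Must lie in [0, 0.5).
    """

    pitch: float
    radius: float
    n_turns: float
    handedness: str = "left"
    taper_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError(f"helix pitch must be > 0, got {self.pitch}")
        if self.radius < 0:
            raise ValueError(f"helix radius must be >= 0, got {self.radius}")
        if not self.n_turns > 0:
            raise ValueError(f"n_turns must be > 0, got {self.n_turns}")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")
        if not 0.0 <= self.taper_fraction < 0.5:
            raise ValueError("taper_fraction must be in [0, 0.5)")

    @property
    def contour_length(self) -> float:
        """Closed-form contour length of the untapered helix, um."""
        per_turn = math.sqrt(self.pitch**2 + (2 * math.pi * self.radius) ** 2)
        return self.n_turns * per_turn

    @property
    def axial_length(self) -> float:
        return self.n_turns * self.pitch


@dataclass(frozen=True)
class CellBody:
    """Capsule cell body: cylinder of radius ``radius`` with hemispherical
    caps; ``length`` is the pole-to-pole extent H."""

    length: float = 2.5
    radius: float = 0.40

    def __post_init__(self) -> None:
        if not self.length > 2 * self.radius > 0:
            raise ValueError(
                f"capsule requires H > 2a > 0 (H={self.length}, a={self.radius})"
            )

    @property
    def cylinder_length(self) -> float:
        return self.length - 2 * self.radius

    @property
    def area(self) -> float:
        return capsule_area(self.radius, self.length)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from points to the capsule surface (axis = z,
        centered at the origin); negative inside."""
        p = np.atleast_2d(points)
        zc = np.clip(p[:, 2], -self.cylinder_length / 2, self.cylinder_length / 2)
        d_axis = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2 + (p[:, 2] - zc) ** 2)
        return d_axis - self.radius


def capsule_area(a: float, H: float) -> float:
    """Analytic surface area of a capsule of radius *a*, pole-to-pole length H."""
    return 2 * math.pi * a * (H - 2 * a) + 4 * math.pi * a**2


@dataclass(frozen=True)
class TubeGeometry:
    """Circular confining tube, meshed as a finite open-ended section.

    ``truncation_length`` must be at least 8 cell lengths so that the open
    ends do not contaminate the mobility solve (audited by doubling).
    """

    radius: float
    truncation_length: float = 25.0
    body_length_ref: float = 2.5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("tube radius must be > 0")
        if self.truncation_length < 8 * self.body_length_ref:
            raise ValueError(
                "truncation_length must be >= 8 cell lengths "
                f"({self.truncation_length} < {8 * self.body_length_ref})"
            )


@dataclass(frozen=True)
class SwimmerConfiguration:
    """Full swimmer description: body + filament + wrapping mode.

    In wrapped mode the filament winds coaxially around the body at radius
    ``body.radius + wrap_clearance`` with the coiled-form pitch.
    """

    mode: str  # {"unwrapped", "wrapped"}
    body: CellBody
    helix: HelixShape
    wrap_clearance: float = 0.05
    attachment_pole: str = "rear"  # filament emerges from this pole
    filament_radius: float = 0.02

    def __post_init__(self) -> None:
        if self.mode not in ("unwrapped", "wrapped"):
            raise ValueError("mode must be 'unwrapped' or 'wrapped'")
        if self.attachment_pole not in ("front", "rear"):
            raise ValueError("attachment_pole must be 'front' or 'rear'")
        if self.mode == "wrapped" and not self.wrap_clearance > self.filament_radius:
            raise ValueError(
                "wrap clearance must exceed the filament radius "
                f"({self.wrap_clearance} <= {self.filament_radius})"
            )

    @property
    def winding_radius(self) -> float:
        return self.body.radius + self.wrap_clearance


def max_radial_extent(config: SwimmerConfiguration) -> float:
    """Widest radial extent of the swimmer surface from the body axis, um.

    For the wrapped mode this includes the wound filament (winding radius
    plus filament radius); for the unwrapped mode it is the larger of the
    body radius and the helix envelope.
    """
    if config.mode == "wrapped":
        return max(config.body.radius,
                   config.winding_radius + config.filament_radius)
    return max(config.body.radius, config.helix.radius + config.filament_radius)


def normalized_gap(config: SwimmerConfiguration, tube: TubeGeometry) -> float:
    """Normalized gap DeltaR / (H/2): radial clearance between the widest
    swimmer surface and the tube wall, normalized by half the cell length."""
    dR = tube.radius - max_radial_extent(config)
    return dR / (config.body.length / 2)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

#: Polymorphic-form helix presets: the normal form (trailing run) and the
#: coiled form adopted on wrapping.
HELIX_PRESETS = {
    "normal": HelixShape(pitch=2.0, radius=0.3, n_turns=3.0,
                         handedness="left", taper_fraction=0.1),
    "coiled": HelixShape(pitch=1.0, radius=0.5, n_turns=2.5,
                         handedness="left", taper_fraction=0.1),
}

_BODY_DEFAULT = CellBody(length=2.5, radius=0.40)


def load_presets(path=None) -> dict:
    """Load named geometries from a presets YAML file.

    With no path, reads the packaged ``data/presets.yaml`` (which mirrors
    the built-in presets).  Returns a mapping name -> SwimmerConfiguration.
    """
    import yaml
    if path is None:
        from importlib import resources
        text = (resources.files("flagwrap") / "data" /
                "presets.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    body = CellBody(cfg["body"]["length_um"], cfg["body"]["radius_um"])
    helices = {
        name: HelixShape(h["pitch_um"], h["radius_um"], h["n_turns"],
                         h.get("handedness", "left"),
                         h.get("taper_fraction", 0.0))
        for name, h in cfg["helices"].items()
    }
    out = {}
    for name, c in cfg["configurations"].items():
        out[name] = SwimmerConfiguration(
            c["mode"], body, helices[c["helix"]],
            wrap_clearance=c.get("wrap_clearance_um", 0.05),
            filament_radius=cfg.get("filament_radius_um", 0.02))
    return out


def preset_config(name: str) -> SwimmerConfiguration:
    """Named swimmer configurations.

    ``"normal"`` — unwrapped swimmer with the normal-form helix;
    ``"coiled"`` — unwrapped swimmer carrying the coiled-form helix;
    ``"wrapped-default"`` — wrapped swimmer (coiled-form parameters wound
    around the body at clearance 0.05 um).
    """
    if name == "normal":
        return SwimmerConfiguration("unwrapped", _BODY_DEFAULT, HELIX_PRESETS["normal"])
    if name == "coiled":
        return SwimmerConfiguration("unwrapped", _BODY_DEFAULT, HELIX_PRESETS["coiled"])
    if name == "wrapped-default":
        return SwimmerConfiguration("wrapped", _BODY_DEFAULT, HELIX_PRESETS["coiled"])
    raise KeyError(f"unknown preset {name!r}; use normal|coiled|wrapped-default")


# --------------------------------------------------------------------------
# centerlines
# --------------------------------------------------------------------------

def build_helix_centerline(helix: HelixShape, n_points: int):
    """Ordered points on a (tapered) helix along +z starting at the origin.

    Returns ``(points, contour_length)`` where *points* is an (n, 3) array
    and *contour_length* the polyline arc length.  Requires at least 16
    points per turn.
    """
    min_pts = max(2, int(math.ceil(16 * helix.n_turns)))
    if n_points < min_pts:
        raise ValueError(
            f"n_points={n_points} too coarse; need >= 16 per turn ({min_pts})"
        )
    phi_max = 2 * math.pi * helix.n_turns
    phi = np.linspace(0.0, phi_max, n_points)
    frac = phi / phi_max  # ~ contour fraction for a uniform helix
    r = np.full_like(phi, helix.radius)
    if helix.taper_fraction > 0:
        r = helix.radius * np.clip(frac / helix.taper_fraction, 0.0, 1.0)
    sign = 1.0 if helix.handedness == "right" else -1.0
    pts = np.column_stack([
        r * np.cos(phi),
        sign * r * np.sin(phi),
        helix.pitch * phi / (2 * math.pi),
    ])
    pts[:, 0] -= r[0] * 1.0  # start exactly at the origin
    length = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return pts, length


def build_wrapped_centerline(body: CellBody, helix: HelixShape,
                             clearance: float, n_points: int = 400):
    """Centerline of a filament wound around the body like a screw thread.

    The body sits with its axis along z, centered at the origin; the
    attachment pole is at z = +H/2.  The filament starts on the axis just
    above the pole, spirals over the (offset) spherical cap, winds around
    the cylindrical section at radius ``a + clearance`` with the coiled-form
    pitch, and any remaining contour length continues as a free helix of the
    same radius and pitch beyond the far pole.

    Returns ``(points, info)`` with ``info`` containing the contour length,
    wrap turn count over the body, and the winding radius.
    """
    if clearance <= 0:
        raise ValueError("wrap clearance must be > 0")
    a, H, p = body.radius, body.length, helix.pitch
    rw = a + clearance
    L_target = helix.contour_length
    # the wound curve descends in z as phi grows, which flips the apparent
    # chirality of (cos, sin, -z): a left-handed filament winds with +sin
    sign = -1.0 if helix.handedness == "right" else 1.0
    z_cap = H / 2 - a          # center of the attachment cap
    z_top = z_cap + rw         # start point height (on axis + clearance)

    # dense parametrization by winding angle; z falls linearly with angle
    # (screw of pitch p); radial coordinate follows the offset capsule.
    phi_dense = np.linspace(0.0, 2 * math.pi * (L_target / p + 2), 20000)
    z = z_top - p * phi_dense / (2 * math.pi)
    rad = np.where(
        z > z_cap,
        np.sqrt(np.clip(rw**2 - (z - z_cap) ** 2, 0.0, None)),
        rw,
    )
    pts = np.column_stack([rad * np.cos(phi_dense),
                           sign * rad * np.sin(phi_dense), z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < L_target:
        raise ValueError("internal: dense parametrization too short")
    # resample to n_points uniformly in arc length, truncated at L_target
    s_new = np.linspace(0.0, L_target, n_points)
    out = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])
    z_end_body = -H / 2
    phi_at = np.interp([z_top, z_end_body][::-1],
                       z[::-1], phi_dense[::-1])
    wrap_turns = float(abs(phi_at[1] - phi_at[0]) / (2 * math.pi))
    covered = min(out[:, 2].min(), z_end_body)
    info = {
        "contour_length": L_target,
        "winding_radius": rw,
        "wrap_turns_over_body": min(wrap_turns,
                                    float((z_top - max(out[-1, 2], z_end_body))
                                          / p)),
        "reaches_far_pole": bool(out[-1, 2] <= z_end_body),
    }
    return out, info


# --------------------------------------------------------------------------
# surface meshes
# --------------------------------------------------------------------------

class SurfaceMesh:
    """Labeled triangle surface mesh with per-element quadrature data.

    Attributes
    ----------
    vertices : (V, 3) float array, um
    faces : (F, 3) int array
    label : str — one of {"body", "flagellum", "wall", ...}
    areas : (F,) per-element areas (possibly rescaled to the analytic
        component area so the mesh integrates exactly)
    centroids, normals : (F, 3) arrays; normals are outward unit vectors.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, label: str,
                 analytic_area: float | None = None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.label = label
        v0 = self.vertices[self.faces[:, 0]]
        v1 = self.vertices[self.faces[:, 1]]
        v2 = self.vertices[self.faces[:, 2]]
        cross = np.cross(v1 - v0, v2 - v0)
        nrm = np.linalg.norm(cross, axis=1)
        if np.any(nrm <= 0):
            raise ValueError(f"degenerate triangle in {label!r} mesh")
        self.areas = 0.5 * nrm
        self.normals = cross / nrm[:, None]
        self.centroids = (v0 + v1 + v2) / 3.0
        self.flat_area = float(self.areas.sum())
        if analytic_area is not None:
            # panel weights rescaled so the mesh is an exact-area quadrature
            self.areas = self.areas * (analytic_area / self.flat_area)
        self.area = float(self.areas.sum())

    @property
    def n_elements(self) -> int:
        return len(self.faces)

    def orient_outward(self, reference: str = "centroid",
                       axis_half_length: float | None = None) -> None:
        """Flip faces whose normal points toward the interior.

        ``reference="centroid"`` orients away from the mesh centroid;
        ``reference="axis"`` orients away from the z-axis segment of the
        given half-length (used for capsules/tubes/swept filaments).
        """
        if reference == "centroid":
            out = self.centroids - self.vertices.mean(axis=0)
        else:
            c = self.centroids.copy()
            if axis_half_length is not None:
                c[:, 2] = c[:, 2] - np.clip(c[:, 2], -axis_half_length,
                                            axis_half_length)
            else:
                c[:, 2] = 0.0
            out = c
        flip = np.einsum("ij,ij->i", self.normals, out) < 0
        self.faces[flip] = self.faces[flip][:, ::-1]
        self.normals[flip] *= -1.0

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def _resolution_to_h(resolution: float) -> float:
    """Convert target element density (elements per um^2) to a linear
    element size (two triangles per h x h quad)."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    return math.sqrt(2.0 / resolution)


def _revolve(profile_r: np.ndarray, profile_z: np.ndarray, n_az: int,
             close_poles: bool = True):
    """Triangulate a surface of revolution about the z axis.

    Profile runs pole-to-pole (or edge-to-edge); rings with r ~ 0 collapse
    into pole vertices with triangle fans.
    """
    theta = np.linspace(0.0, 2 * math.pi, n_az, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = []
    ring_idx = []
    for r, z in zip(profile_r, profile_z):
        if close_poles and r < 1e-9:
            ring_idx.append(("pole", len(verts)))
            verts.append((0.0, 0.0, z))
        else:
            ring_idx.append(("ring", len(verts)))
            verts.extend(zip(r * ct, r * st, np.full(n_az, z)))
    faces = []
    for (kind0, i0), (kind1, i1) in zip(ring_idx[:-1], ring_idx[1:]):
        if kind0 == "pole" and kind1 == "ring":
            for k in range(n_az):
                faces.append((i0, i1 + k, i1 + (k + 1) % n_az))
        elif kind0 == "ring" and kind1 == "pole":
            for k in range(n_az):
                faces.append((i0 + k, i1, i0 + (k + 1) % n_az))
        elif kind0 == "ring" and kind1 == "ring":
            for k in range(n_az):
                k2 = (k + 1) % n_az
                faces.append((i0 + k, i1 + k, i1 + k2))
                faces.append((i0 + k, i1 + k2, i0 + k2))
    return np.asarray(verts, float), np.asarray(faces, np.int64)


def build_capsule_mesh(body: CellBody, resolution: float = 200.0,
                       label: str = "body") -> SurfaceMesh:
    """Watertight capsule mesh (axis z, centered at the origin), with panel
    areas rescaled to the analytic capsule area."""
    h = _resolution_to_h(resolution)
    a, Lc = body.radius, body.cylinder_length
    n_cap = max(4, int(math.ceil((math.pi / 2 * a) / h)))
    n_cyl = max(2, int(math.ceil(Lc / h)))
    n_az = max(12, int(math.ceil(2 * math.pi * a / h)))
    th = np.linspace(0.0, math.pi / 2, n_cap + 1)
    # top cap (pole to equator), cylinder, bottom cap
    r_prof = np.concatenate([
        a * np.sin(th),
        np.full(n_cyl - 1, a),
        a * np.sin(th[::-1]),
    ])
    z_prof = np.concatenate([
        Lc / 2 + a * np.cos(th),
        np.linspace(Lc / 2, -Lc / 2, n_cyl + 1)[1:-1],
        -Lc / 2 - a * np.cos(th[::-1]),
    ])
    verts, faces = _revolve(r_prof, z_prof, n_az)
    mesh = SurfaceMesh(verts, faces, label, analytic_area=body.area)
    mesh.orient_outward("axis", axis_half_length=Lc / 2)
    return mesh


def build_sphere_mesh(radius: float, resolution: float = 200.0,
                      label: str = "body") -> SurfaceMesh:
    """Watertight UV-sphere mesh with exact-area panel weights."""
    h = _resolution_to_h(resolution)
    n_pol = max(8, int(math.ceil(math.pi * radius / h)))
    n_az = max(12, int(math.ceil(2 * math.pi * radius / h)))
    th = np.linspace(0.0, math.pi, n_pol + 1)
    verts, faces = _revolve(radius * np.sin(th), radius * np.cos(th), n_az)
    mesh = SurfaceMesh(verts, faces, label,
                       analytic_area=4 * math.pi * radius**2)
    mesh.orient_outward("centroid")
    return mesh


def build_tube_wall_mesh(tube: TubeGeometry, resolution: float = 200.0,
                         fine_half_length: float = 4.0,
                         growth: float = 1.35) -> SurfaceMesh:
    """Open-ended tube wall mesh, axially graded: element size ~h within
    ``fine_half_length`` of the midplane, growing geometrically toward the
    truncated ends.  Wide tubes (wall far from the swimmer) are coarsened
    proportionally to the radius, since the hydrodynamic influence of the
    wall decays with distance.  Normals point away from the axis."""
    h = _resolution_to_h(resolution) * max(1.0, tube.radius / 0.8)
    half = tube.truncation_length / 2
    z = [0.0]
    dz = h
    while z[-1] < half:
        z.append(min(z[-1] + dz, half))
        if z[-1] > fine_half_length:
            dz *= growth
    z = np.asarray(z)
    z_prof = np.concatenate([-z[::-1], z[1:]])
    n_az = max(12, int(math.ceil(2 * math.pi * tube.radius / h)))
    verts, faces = _revolve(np.full_like(z_prof, tube.radius), z_prof, n_az,
                            close_poles=False)
    analytic = 2 * math.pi * tube.radius * tube.truncation_length
    mesh = SurfaceMesh(verts, faces, "wall", analytic_area=analytic)
    mesh.orient_outward("axis", axis_half_length=half)
    return mesh


def _parallel_transport_frames(points: np.ndarray):
    """Orthonormal frames (n1, n2) transported along a polyline."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    n1 = np.zeros_like(tang)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tang[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1[0] = np.cross(tang[0], ref)
    n1[0] /= np.linalg.norm(n1[0])
    for i in range(1, len(points)):
        v = np.cross(tang[i - 1], tang[i])
        s = np.linalg.norm(v)
        c = float(np.dot(tang[i - 1], tang[i]))
        if s < 1e-12:
            n1[i] = n1[i - 1]
        else:
            v = v / s
            # Rodrigues rotation of the previous normal
            n = n1[i - 1]
            n1[i] = (n * c + np.cross(v, n) * s
                     + v * np.dot(v, n) * (1 - c))
        n1[i] -= np.dot(n1[i], tang[i]) * tang[i]
        n1[i] /= np.linalg.norm(n1[i])
    n2 = np.cross(tang, n1)
    return tang, n1, n2


def sweep_tube_mesh(centerline: np.ndarray, tube_radius: float,
                    resolution: float = 200.0,
                    label: str = "flagellum") -> SurfaceMesh:
    """Watertight tube mesh swept along a centerline (capped ends).

    Azimuthal count is at least 6; panel areas are rescaled by the polygon
    perimeter factor so rings integrate the circular cross-section exactly.
    """
    h = _resolution_to_h(resolution)
    seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_axial = max(8, int(math.ceil(s[-1] / min(h, 5 * tube_radius))))
    s_new = np.linspace(0.0, s[-1], n_axial + 1)
    cl = np.column_stack([np.interp(s_new, s, centerline[:, k])
                          for k in range(3)])
    tang, n1, n2 = _parallel_transport_frames(cl)
    n_az = max(6, int(math.ceil(2 * math.pi * tube_radius / h)))
    theta = np.linspace(0.0, 2 * math.pi, n_az, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    verts = [cl[0] - 0.0]  # start cap apex
    faces = []
    ring_start = []
    for i in range(len(cl)):
        ring_start.append(len(verts))
        ring = (cl[i][None, :] + tube_radius * (np.outer(ct, n1[i])
                                                + np.outer(st, n2[i])))
        verts.extend(ring)
    verts.append(cl[-1])
    verts = np.asarray(verts)
    # start fan
    for k in range(n_az):
        faces.append((0, ring_start[0] + (k + 1) % n_az, ring_start[0] + k))
    for i in range(len(cl) - 1):
        i0, i1 = ring_start[i], ring_start[i + 1]
        for k in range(n_az):
            k2 = (k + 1) % n_az
            faces.append((i0 + k, i1 + k, i1 + k2))
            faces.append((i0 + k, i1 + k2, i0 + k2))
    apex_end = len(verts) - 1
    i0 = ring_start[-1]
    for k in range(n_az):
        faces.append((apex_end, i0 + k, i0 + (k + 1) % n_az))
    # perimeter correction: inscribed n-gon vs circle
    corr = (math.pi / n_az) / math.sin(math.pi / n_az)
    mesh = SurfaceMesh(verts, np.asarray(faces, np.int64), label)
    mesh.areas = mesh.areas * corr
    mesh.area = float(mesh.areas.sum())
    # orient normals away from the local centerline point
    nearest = np.argmin(
        np.linalg.norm(mesh.centroids[:, None, :] - cl[None, :, :], axis=2),
        axis=1)
    out = mesh.centroids - cl[nearest]
    tcomp = np.einsum("ij,ij->i", out, tang[nearest])[:, None] * tang[nearest]
    radial = out - tcomp
    bad = np.linalg.norm(radial, axis=1) < 1e-9
    radial[bad] = out[bad]
    flip = np.einsum("ij,ij->i", mesh.normals, radial) < 0
    mesh.faces[flip] = mesh.faces[flip][:, ::-1]
    mesh.normals[flip] *= -1.0
    return mesh


def _flagellum_centerline(config: SwimmerConfiguration, n_points: int = 300):
    """Filament centerline in the body frame (body axis z, centered at 0).

    The filament emerges from the attachment pole.  For ``attachment_pole ==
    "rear"`` it extends toward +z when unwrapped, and wraps back over the
    body toward -z when wrapped.
    """
    H = config.body.length
    if config.mode == "unwrapped":
        pts, _ = build_helix_centerline(config.helix, n_points)
        # small standoff in place of the (unmodeled) hook
        pts = pts + np.array([0.0, 0.0, H / 2 + config.wrap_clearance])
    else:
        pts, _ = build_wrapped_centerline(config.body, config.helix,
                                          config.wrap_clearance, n_points)
    if config.attachment_pole == "front":
        pts = pts * np.array([1.0, -1.0, -1.0])  # proper mirror through z=0
    return pts


def build_surface_meshes(config: SwimmerConfiguration,
                         tube: TubeGeometry | None = None,
                         resolution: float = 200.0,
                         flagellum_resolution: float | None = None,
                         wall_resolution: float | None = None) -> dict:
    """Build the labeled mesh set for a swimmer (+ optional tube wall).

    ``resolution`` is the target element density (elements per um^2) for the
    body; the filament uses ``flagellum_resolution`` (default: 4x body, since
    the filament is much more slender) and the wall ``wall_resolution``
    (default: equal to body).  Raises if the wrapped filament would
    intersect the body or the wall.
    """
    if flagellum_resolution is None:
        flagellum_resolution = 4 * resolution
    if wall_resolution is None:
        wall_resolution = resolution
    cl = _flagellum_centerline(config)
    # clearance check, excluding the tapered attachment region
    skip = max(2, int(0.05 * len(cl)))
    dist = config.body.surface_distance(cl[skip:])
    min_clear = float(dist.min())
    if min_clear < config.filament_radius:
        raise ValueError(
            "flagellum centerline intersects the cell body "
            f"(min surface clearance {min_clear:.4f} um <= filament radius "
            f"{config.filament_radius} um); increase wrap_clearance")
    meshes = {
        "body": build_capsule_mesh(config.body, resolution),
        "flagellum": sweep_tube_mesh(cl, config.filament_radius,
                                     flagellum_resolution),
    }
    if tube is not None:
        extent = max_radial_extent(config)
        if tube.radius - extent <= 1e-6:
            raise ValueError(
                f"swimmer (radial extent {extent:.3f} um) touches the tube "
                f"wall (radius {tube.radius:.3f} um)")
        rad_cl = np.sqrt(cl[:, 0] ** 2 + cl[:, 1] ** 2)
        if np.any(rad_cl + config.filament_radius >= tube.radius):
            raise ValueError("flagellum touches the tube wall")
        fine = abs(cl[:, 2]).max() * 1.1
        meshes["wall"] = build_tube_wall_mesh(tube, wall_resolution,
                                              fine_half_length=float(fine))
    return meshes
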