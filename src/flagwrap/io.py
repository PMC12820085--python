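"""File output: legacy-ASCII VTK, CSV mesh/track tables, metadata headers.

All files are plain text; units are um, s, pN throughout (as in the rest of
the package).  Every JSON artifact carries a ``metadata`` block with the
package version, the seed, and a hash of the configuration that produced
it, so outputs can be traced back to their run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_metadata(config: dict, seed: int | None = None) -> dict:
    from . import __version__
    return {
        "package": "flagwrap",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }


def write_json(path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return str(obj)


def write_vtk_mesh(path, mesh) -> None:
    """Legacy-ASCII VTK PolyData of a triangle SurfaceMesh."""
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"flagwrap mesh {mesh.label}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_vtk_polyline(path, points: np.ndarray, name: str = "centerline"
                       ) -> None:
    """Legacy-ASCII VTK PolyData polyline (e.g. a filament centerline)."""
    pts = np.asarray(points)
    n = len(pts)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"flagwrap {name}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"LINES 1 {n + 1}\n")
        fh.write(" ".join([str(n)] + [str(i) for i in range(n)]) + "\n")


def write_vtk_points(path, points: np.ndarray, vectors: np.ndarray,
                     name: str = "flow") -> None:
    """Legacy-ASCII VTK point cloud with a vector field (flow samples)."""
    pts = np.asarray(points)
    vec = np.nan_to_num(np.asarray(vectors))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"flagwrap {name}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        fh.write(f"POINT_DATA {len(pts)}\nVECTORS velocity float\n")
        for u in vec:
            fh.write(f"{u[0]:.6g} {u[1]:.6g} {u[2]:.6g}\n")


def mesh_to_table(mesh) -> pd.DataFrame:
    """Per-element table: centroid, outward normal, area, label."""
    c, nrm = mesh.centroids, mesh.normals
    return pd.DataFrame({
        "cx_um": c[:, 0], "cy_um": c[:, 1], "cz_um": c[:, 2],
        "nx": nrm[:, 0], "ny": nrm[:, 1], "nz": nrm[:, 2],
        "area_um2": mesh.areas,
        "label": mesh.label,
    })


def write_mesh_csv(path, meshes: dict) -> None:
    pd.concat([mesh_to_table(m) for m in meshes.values()],
              ignore_index=True).to_csv(path, index=False)


def tracks_to_table(tracks) -> pd.DataFrame:
    """Tidy track table in the dialect ``read_tracks`` consumes."""
    frames = []
    for tr in tracks:
        d = {
            "track_id": tr.track_id,
            "frame": np.arange(len(tr)),
            "time_s": tr.time_s,
            "x_um": tr.x_um,
        }
        if tr.is_2d:
            d["y_um"] = tr.y_um
        frames.append(pd.DataFrame(d))
    return pd.concat(frames, ignore_index=True)


def write_tracks_csv(path, tracks) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tracks_to_table(tracks).to_csv(path, index=False)


def write_angle_csv(path, trace) -> None:
    pd.DataFrame({"time_s": trace.time_s,
                  "angle_rad": trace.angle_rad}).to_csv(path, index=False)


def read_angle_csv(path):
    from .hook_stiffness import AngleTrace
    df = pd.read_csv(path)
    return AngleTrace(df["time_s"].to_numpy(), df["angle_rad"].to_numpy())
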