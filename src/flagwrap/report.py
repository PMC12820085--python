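"""Report assembly: one markdown summary over a directory of stage outputs.

Sections appear only for artifacts that are present (gap sweep, wrapping
phase table, trajectory statistics, MSD); each section cites the config
hash of the run that produced its artifact, and conflicting package
versions across artifacts are surfaced in a warnings section.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _meta_of(payload: dict) -> dict:
    return payload.get("metadata", {}) if isinstance(payload, dict) else {}


def build_report(artifact_dir) -> str:
    """Collect known artifacts under ``artifact_dir`` into one document."""
    root = Path(artifact_dir)
    parts = ["# flagwrap run report\n"]
    versions = {}
    n_sections = 0

    sweep = root / "sweep.csv"
    if sweep.exists():
        df = pd.read_csv(sweep)
        parts.append("## Confinement gap sweep\n")
        parts.append(df.to_markdown(index=False))
        meta = root / "sweep.meta.json"
        if meta.exists():
            m = _meta_of(json.loads(meta.read_text()))
            versions[str(sweep)] = m.get("version")
            parts.append(f"\nconfig hash: `{m.get('config_hash')}`\n")
        n_sections += 1

    phase = root / "phase.csv"
    if phase.exists():
        df = pd.read_csv(phase)
        parts.append("## Wrapping phase table\n")
        modal = (df.groupby(["ahook_ratio", "ca_ratio"])["label"]
                 .agg(lambda s: s.mode()[0]).reset_index())
        parts.append(modal.to_markdown(index=False))
        n_sections += 1

    stats = root / "stats.json"
    if stats.exists():
        payload = json.loads(stats.read_text())
        parts.append("## Quasi-1D run statistics\n")
        nd = payload.get("net_displacement_um_per_min", {})
        parts.append(f"- tracks: {payload.get('n_tracks')}")
        parts.append(f"- mean net displacement: {nd.get('mean'):.1f} um/min")
        if "run_time_constants" in payload:
            rc = payload["run_time_constants"]
            parts.append(f"- tau_forward = {rc['tau_forward_s']:.2f} s, "
                         f"tau_backward = {rc['tau_backward_s']:.2f} s")
        m = _meta_of(payload)
        versions[str(stats)] = m.get("version")
        parts.append(f"- config hash: `{m.get('config_hash')}`\n")
        n_sections += 1

    msd = root / "msd.csv"
    if msd.exists():
        df = pd.read_csv(msd)
        parts.append("## MSD\n")
        fit = msd.with_suffix(".fit.json")
        if fit.exists():
            f = json.loads(fit.read_text())
            parts.append(f"- drift v = {f.get('v_um_per_s'):.3f} um/s; "
                         f"D = {f.get('D_um2_per_s'):.4f} um^2/s")
            versions[str(msd)] = _meta_of(f).get("version")
        parts.append(f"- {len(df)} lag points, max lag "
                     f"{df['lag_s'].iloc[-1]:.1f} s\n")
        n_sections += 1

    if n_sections == 0:
        raise ValueError(f"no known artifacts found under {root}")
    vset = {v for v in versions.values() if v}
    if len(vset) > 1:
        parts.append("## Warnings\n")
        parts.append(f"- artifacts produced by multiple package versions: "
                     f"{sorted(vset)}")
    return "\n".join(parts) + "\n"
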