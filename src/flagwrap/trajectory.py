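"""Quasi-1D motility statistics.

Pipeline for single-cell tracks in a narrow channel (and for bead tracks in
an open chamber): run segmentation with a hysteresis threshold, exponential
run-duration fits, duration-binned forward bias, windowed net displacement,
MSD decomposition into drift and diffusion, diffusion-confinement ratios,
and the competitive index of a co-infection assay.

Tracks are consumed as tidy tables (CSV columns ``track_id, frame, time_s,
x_um[, y_um]``); no image processing happens here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "RunSegment",
    "read_tracks",
    "segment_runs",
    "fit_run_time_constant",
    "forward_bias_by_duration",
    "net_displacement_per_minute",
    "signed_mean_displacement",
    "compute_msd",
    "fit_msd",
    "diffusion_confinement_ratio",
    "competitive_index",
]


@dataclass
class Track:
    """Single-particle track, uniform sampling, positions in um.

    1-D channel tracks use ``x``; 2-D chamber tracks carry ``y`` as well.
    2-D tracks can be projected onto their principal axis for quasi-1D
    analysis (the projection axis is recorded).
    """

    track_id: str
    time_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.x_um = np.asarray(self.x_um, float)
        if self.y_um is not None:
            self.y_um = np.asarray(self.y_um, float)
        if len(self.time_s) != len(self.x_um):
            raise ValueError("time and position length mismatch")
        dt = np.diff(self.time_s)
        if len(dt) and np.any(dt <= 0):
            raise ValueError(f"track {self.track_id}: time not strictly increasing")
        if len(dt) > 1 and np.ptp(dt) > 0.01 * dt.mean():
            raise ValueError(f"track {self.track_id}: sampling not uniform within 1%")

    @property
    def dt(self) -> float:
        return float(np.diff(self.time_s).mean()) if len(self.time_s) > 1 else math.nan

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def is_2d(self) -> bool:
        return self.y_um is not None

    def __len__(self) -> int:
        return len(self.time_s)

    def project_principal_axis(self) -> "Track":
        """Project a 2-D track onto its principal (largest-variance) axis."""
        if not self.is_2d:
            return self
        xy = np.column_stack([self.x_um, self.y_um])
        xy = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        axis = vt[0]
        proj = xy @ axis
        meta = dict(self.meta, projection_axis=axis.tolist())
        return Track(self.track_id, self.time_s.copy(), proj, None, meta)


@dataclass(frozen=True)
class RunSegment:
    """One directional run between reversals."""

    direction: str      # {"forward", "backward"}
    start_s: float
    duration_s: float
    displacement_um: float
    censored: bool = False   # touches a track end (incomplete duration)


def read_tracks(path) -> list[Track]:
    """Read tracker-exported track tables.

    Expects columns ``track_id, frame, time_s, x_um`` and optionally
    ``y_um``.  Tracks with non-monotone time or duplicated frames are
    rejected with a diagnostic warning; malformed rows are reported with
    their line numbers.  An empty file yields an empty list with a warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no tracks found")
        return []
    required = {"track_id", "frame", "time_s", "x_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = ~np.isfinite(df[["time_s", "x_um"]]).all(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        warnings.warn(f"{path}: dropping malformed rows at lines {lines}")
        df = df[~bad]
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        if sub["frame"].duplicated().any():
            warnings.warn(f"track {tid}: duplicated frame, rejected")
            continue
        try:
            tracks.append(Track(
                str(tid), sub["time_s"].to_numpy(), sub["x_um"].to_numpy(),
                sub["y_um"].to_numpy() if "y_um" in sub else None))
        except ValueError as exc:
            warnings.warn(f"track {tid} rejected: {exc}")
    return tracks


# --------------------------------------------------------------------------
# run segmentation and statistics
# --------------------------------------------------------------------------

def segment_runs(track: Track, min_reversal_displacement: float = 0.2
                 ) -> list[RunSegment]:
    """Split a 1-D track into alternating directional runs.

    A direction change is declared only when the cumulative displacement
    against the current direction exceeds ``min_reversal_displacement``
    (hysteresis, um): sub-threshold jitter does not break a run.  Segments
    tile the track; the reversal point is placed at the extremum reached
    before the counter-movement.  First and last segments are flagged as
    censored (their true durations are cut by the track ends).
    """
    if track.is_2d:
        track = track.project_principal_axis()
    x, t = track.x_um, track.time_s
    n = len(x)
    if n < 3:
        return []
    thr = float(min_reversal_displacement)
    # initial direction: first excursion that exceeds the threshold
    direction = 0
    ext_i = 0           # index of the running extremum of current run
    start_i = 0
    imin = imax = 0     # extrema while the direction is still undecided
    segments = []
    for i in range(1, n):
        if direction == 0:
            if x[i] < x[imin]:
                imin = i
            if x[i] > x[imax]:
                imax = i
            if x[i] - x[imin] > thr:
                direction = 1
                ext_i = i
            elif x[imax] - x[i] > thr:
                direction = -1
                ext_i = i
            continue
        if direction * (x[i] - x[ext_i]) >= 0:
            ext_i = i  # still advancing
        elif direction * (x[ext_i] - x[i]) > thr:
            # reversal confirmed: close the run at the extremum
            segments.append(RunSegment(
                "forward" if direction > 0 else "backward",
                start_s=float(t[start_i]),
                duration_s=float(t[ext_i] - t[start_i]),
                displacement_um=float(x[ext_i] - x[start_i]),
                censored=start_i == 0,
            ))
            start_i = ext_i
            direction = -direction
            ext_i = i
    # terminal (censored) run
    final_dir = direction if direction != 0 else (
        1 if x[-1] >= x[0] else -1)
    segments.append(RunSegment(
        "forward" if final_dir > 0 else "backward",
        start_s=float(t[start_i]),
        duration_s=float(t[-1] - t[start_i]),
        displacement_um=float(x[-1] - x[start_i]),
        censored=True,
    ))
    return [s for s in segments if s.duration_s > 0]


def fit_run_time_constant(durations, n_boot: int = 500, seed: int = 0,
                          min_duration: float = 0.0) -> dict:
    """Maximum-likelihood exponential fit of run durations.

    For an exponential with detection floor ``min_duration`` the MLE is
    tau = mean(durations) - min_duration.  Returns the estimate, a
    percentile bootstrap CI, and a warning flag when fewer than 10 runs are
    supplied (the estimate is still produced).
    """
    d = np.asarray(list(durations), float)
    if len(d) == 0:
        raise ValueError("no durations supplied")
    if np.any(d < min_duration):
        raise ValueError("durations below the stated detection floor")
    tau = float(d.mean() - min_duration)
    rng = np.random.default_rng(seed)
    if len(d) > 1:
        boots = d[rng.integers(0, len(d), (n_boot, len(d)))].mean(axis=1) \
            - min_duration
        ci = (float(np.percentile(boots, 2.5)),
              float(np.percentile(boots, 97.5)))
    else:
        ci = (tau, tau)
    return {
        "tau_s": tau,
        "ci_95": ci,
        "n": len(d),
        "warning": "fewer than 10 durations" if len(d) < 10 else "",
        "zero_width_ci": bool(np.allclose(d, d[0])),
    }


def fit_alternating_time_constants(dur_forward, dur_backward,
                                   detection_floor_s: float) -> dict:
    """Merge-corrected exponential time constants for alternating runs.

    Hysteresis segmentation cannot see counter-runs shorter than the
    detection floor t_min ~ threshold/speed + frame/2: such runs are merged
    into their neighbours, inflating observed durations.  Modelling runs as
    alternating exponentials where a reversal is detected only when the new
    run outlasts t_min, the observed mean durations are

        m_f = (tau_f + t_min) + q_b/(1-q_b) * (s(tau_b) + tau_f)

    (and symmetrically for m_b), with q = 1 - exp(-t_min/tau) the miss
    probability and s(tau) = E[run | run < t_min] the mean merged stub.
    This inverts those two equations for (tau_f, tau_b).  A practical
    floor is threshold/speed plus a quarter frame: the quarter frame
    absorbs frame quantization and the second-order effect of missed runs
    leaving a displacement deficit at the running extremum (validated on
    generated run-and-reverse tracks across parameter sets).
    """
    from scipy.optimize import fsolve
    m_f = float(np.mean(dur_forward))
    m_b = float(np.mean(dur_backward))
    t = float(detection_floor_s)
    if t <= 0:
        return {"tau_forward_s": m_f, "tau_backward_s": m_b,
                "detection_floor_s": 0.0, "converged": True}

    def short_mean(tau):
        q = -math.expm1(-t / tau)
        return tau - t * math.exp(-t / tau) / q

    def eqs(p):
        lf, lb = p
        tf, tb = math.exp(lf), math.exp(lb)
        qb = -math.expm1(-t / tb)
        qf = -math.expm1(-t / tf)
        ef = tf + t + qb / (1 - qb) * (short_mean(tb) + tf)
        eb = tb + t + qf / (1 - qf) * (short_mean(tf) + tb)
        return [ef - m_f, eb - m_b]

    x0 = [math.log(max(m_f - t, 0.05)), math.log(max(m_b - t, 0.05))]
    sol, info, ier, _ = fsolve(eqs, x0, full_output=True)
    return {
        "tau_forward_s": float(math.exp(sol[0])),
        "tau_backward_s": float(math.exp(sol[1])),
        "detection_floor_s": t,
        "observed_mean_forward_s": m_f,
        "observed_mean_backward_s": m_b,
        "converged": ier == 1,
        "n_forward": len(dur_forward),
        "n_backward": len(dur_backward),
    }


def run_speed(segments) -> float:
    """Median run speed |displacement| / duration over detected runs."""
    segs = [s for s in segments if not s.censored and s.duration_s > 0]
    if not segs:
        raise ValueError("no complete runs")
    return float(np.median([abs(s.displacement_um) / s.duration_s
                            for s in segs]))


def forward_bias_by_duration(segments, bin_width_s: float = 0.5,
                             include_censored: bool = False) -> pd.DataFrame:
    """Forward-run fraction per run-duration bin.

    Bins of ``bin_width_s`` cover the observed durations; empty bins are
    simply absent from the table (missing, not zero).
    """
    segs = [s for s in segments if include_censored or not s.censored]
    if not segs:
        return pd.DataFrame(columns=["bin_left_s", "bin_right_s",
                                     "forward_fraction", "n"])
    dur = np.array([s.duration_s for s in segs])
    fwd = np.array([s.direction == "forward" for s in segs])
    idx = np.floor(dur / bin_width_s).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sel = idx == k
        rows.append({
            "bin_left_s": k * bin_width_s,
            "bin_right_s": (k + 1) * bin_width_s,
            "forward_fraction": float(fwd[sel].mean()),
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def net_displacement_per_minute(track: Track, window_s: float = 60.0) -> float:
    """Mean absolute displacement over 1-minute windows, um/min.

    Both directions count as positive (channel tracks have no preferred
    sign).  Tracks shorter than one window are scaled up to the window with
    a warning.
    """
    if track.is_2d:
        track = track.project_principal_axis()
    x, t = track.x_um, track.time_s
    T = track.duration
    if T <= 0:
        return 0.0
    if T < window_s:
        warnings.warn(f"track {track.track_id}: shorter than {window_s} s; "
                      "net displacement scaled from the full track")
        return abs(x[-1] - x[0]) * (window_s / T)
    dt = track.dt
    w = int(round(window_s / dt))
    disp = np.abs(x[w:] - x[:-w])
    return float(disp.mean() * (window_s / (w * dt)))


def signed_mean_displacement(tracks, window_s: float = 60.0) -> dict:
    """Per-track signed displacement over the window, with symmetry summary.

    A cohort moving isotropically has mean/median near zero and balanced
    signs.
    """
    vals = []
    for tr in tracks:
        if tr.is_2d:
            tr = tr.project_principal_axis()
        T = tr.duration
        scale = window_s / T if 0 < T < window_s else 1.0
        if T >= window_s:
            w = int(round(window_s / tr.dt))
            vals.append(float(tr.x_um[w] - tr.x_um[0]))
        else:
            vals.append(float((tr.x_um[-1] - tr.x_um[0]) * scale))
    v = np.asarray(vals)
    return {
        "per_track_um": v,
        "mean_um": float(v.mean()),
        "median_um": float(np.median(v)),
        "fraction_positive": float((v > 0).mean()),
    }


# --------------------------------------------------------------------------
# MSD analysis
# --------------------------------------------------------------------------

def compute_msd(tracks, max_lag_fraction: float = 0.25) -> pd.DataFrame:
    """Time-averaged MSD per track, averaged over the cohort.

    Lags run up to ``max_lag_fraction`` of the shortest track.  Columns:
    ``lag_s, msd_um2, n_tracks``.  MSD(0) = 0 by definition.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks")
    dt = tracks[0].dt
    n_min = min(len(tr) for tr in tracks)
    max_lag = max(1, int(n_min * max_lag_fraction))
    lags = np.arange(0, max_lag + 1)
    acc = np.zeros(len(lags))
    cnt = np.zeros(len(lags))
    for tr in tracks:
        pos = (np.column_stack([tr.x_um, tr.y_um]) if tr.is_2d
               else tr.x_um[:, None])
        for j, lag in enumerate(lags):
            if lag == 0:
                acc[j] += 0.0
            else:
                d = pos[lag:] - pos[:-lag]
                acc[j] += float((d**2).sum(axis=1).mean())
            cnt[j] += 1
    return pd.DataFrame({
        "lag_s": lags * dt,
        "msd_um2": acc / cnt,
        "n_tracks": cnt.astype(int),
    })


def fit_msd(msd: pd.DataFrame, dimension: int = 1) -> dict:
    """Fit MSD(tau) = v^2 tau^2 + 2 d D tau by weighted least squares.

    Weights ~ 1/tau (longer lags average fewer independent pairs).  Returns
    drift speed v (um/s) and diffusion coefficient D (um^2/s); slightly
    negative basis coefficients from noise are clipped at zero.
    """
    tau = msd["lag_s"].to_numpy()
    y = msd["msd_um2"].to_numpy()
    sel = tau > 0
    tau, y = tau[sel], y[sel]
    X = np.column_stack([tau**2, 2 * dimension * tau])
    w = 1.0 / tau
    XtW = X.T * w
    coef, *_ = np.linalg.lstsq(XtW @ X, XtW @ y, rcond=None)
    v2, D = coef
    return {
        "v_um_per_s": math.sqrt(max(v2, 0.0)),
        "D_um2_per_s": float(D),
        "v2_raw": float(v2),
        "dimension": dimension,
    }


def diffusion_confinement_ratio(tracks_free, tracks_confined,
                                dim_free: int = 2, dim_confined: int = 1,
                                n_boot: int = 100, seed: int = 0) -> dict:
    """Apparent diffusion coefficients of two bead cohorts and their ratio.

    Fits a linear MSD (drift term retained but expected ~0 for beads);
    warns when the ballistic term dominates (model mismatch).  The CI is a
    track-level bootstrap.
    """
    tracks_free, tracks_confined = list(tracks_free), list(tracks_confined)
    if not tracks_free or not tracks_confined:
        raise ValueError("both cohorts must be non-empty")

    def _D(trs, dim):
        fit = fit_msd(compute_msd(trs), dimension=dim)
        return fit

    fit_f = _D(tracks_free, dim_free)
    fit_c = _D(tracks_confined, dim_confined)
    warn = ""
    msd_f = compute_msd(tracks_free)
    tmax = msd_f["lag_s"].iloc[-1]
    if fit_f["v2_raw"] * tmax > 2 * dim_free * fit_f["D_um2_per_s"] and \
            fit_f["v2_raw"] > 0:
        warn = "ballistic-dominated free cohort: diffusion model mismatch"
    ratio = fit_f["D_um2_per_s"] / fit_c["D_um2_per_s"]
    if n_boot <= 0:
        return {
            "D_free_um2_per_s": fit_f["D_um2_per_s"],
            "D_confined_um2_per_s": fit_c["D_um2_per_s"],
            "ratio": float(ratio),
            "ratio_ci_95": (math.nan, math.nan),
            "warning": warn,
        }
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        bf = [tracks_free[i] for i in
              rng.integers(0, len(tracks_free), len(tracks_free))]
        bc = [tracks_confined[i] for i in
              rng.integers(0, len(tracks_confined), len(tracks_confined))]
        boots.append(_D(bf, dim_free)["D_um2_per_s"]
                     / _D(bc, dim_confined)["D_um2_per_s"])
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return {
        "D_free_um2_per_s": fit_f["D_um2_per_s"],
        "D_confined_um2_per_s": fit_c["D_um2_per_s"],
        "ratio": float(ratio),
        "ratio_ci_95": ci,
        "warning": warn,
    }


def competitive_index(input_swapped: float, input_native: float,
                      output_swapped: float, output_native: float) -> float:
    """Competitive index of a co-infection assay.

    CI = (output_swapped / input_swapped) / (output_native / input_native).
    Inputs must be positive; outputs non-negative; a zero native output
    leaves the index undefined.
    """
    if input_swapped <= 0 or input_native <= 0:
        raise ValueError("input counts must be > 0")
    if output_swapped < 0 or output_native < 0:
        raise ValueError("output counts must be >= 0")
    if output_native == 0:
        raise ValueError("competitive index undefined: zero native output")
    return (output_swapped / input_swapped) / (output_native / input_native)
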