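"""Synthetic data generators for the motility-statistics pipeline.

These generators emulate the statistical structure of the microscopy-derived
inputs: quasi-1D run-and-reverse cell tracks with direction-dependent
exponential run durations (and an optional duration-dependent forward bias),
Brownian bead tracks with a prescribed diffusion coefficient (including a
strongly confinement-reduced regime), Ornstein-Uhlenbeck orientation-angle
traces whose stationary variance encodes a known hook stiffness, and
species-archetype cohorts whose net displacements fall in the observed
wrapper (40-130 um/min) or non-wrapper (0-6 um/min) bands.

Every generator is deterministic given its seed and returns ground-truth
parameters alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hook_stiffness import K_B, AngleTrace
from .trajectory import RunSegment, Track

__all__ = [
    "RunReverseParams",
    "CohortArchetype",
    "gen_run_reverse_track",
    "gen_brownian_track",
    "gen_angle_trace",
    "gen_species_cohort",
    "logistic_bias",
    "ARCHETYPES",
]


@dataclass(frozen=True)
class RunReverseParams:
    """Parameters of a piecewise-ballistic run-and-reverse 1-D track.

    ``bias_logistic`` (optional) is (b0, b1, t0): the probability that the
    run *after* a run of duration d continues the net-forward trend,
    p(d) = b0 + (b1 - b0) / (1 + exp(-(d - t0))); with it unset, directions
    simply alternate (symmetric switchback).
    """

    speed: float = 4.0 / 3.0          # um/s
    tau_forward: float = 0.9          # s
    tau_backward: float = 0.45        # s
    frame_interval: float = 0.1       # s
    duration: float = 60.0            # s
    noise_sd: float = 0.05            # um, localization jitter
    bias_logistic: tuple | None = None

    def __post_init__(self) -> None:
        if self.speed < 0 or self.noise_sd < 0:
            raise ValueError("speed and noise must be >= 0")
        if min(self.tau_forward, self.tau_backward) <= 0:
            raise ValueError("run time constants must be > 0")


def gen_run_reverse_track(params: RunReverseParams, seed: int = 0,
                          track_id: str = "synth") -> tuple[Track, list[RunSegment]]:
    """Generate one run-and-reverse track plus its ground-truth segments.

    Runs have exponentially distributed durations with the direction's time
    constant; the cell moves at constant speed within a run; Gaussian
    positional noise is added on top.  Warns when the frame interval is too
    coarse to resolve the shorter run time constant.
    """
    import warnings
    if params.frame_interval >= min(params.tau_forward,
                                    params.tau_backward) / 5:
        warnings.warn("frame interval >= min(tau)/5: runs are barely "
                      "resolvable; segmentation results will be unreliable")
    rng = np.random.default_rng(seed)
    direction = 1 if rng.random() < 0.5 else -1
    t, x = 0.0, 0.0
    switch_t, switch_x, dirs = [0.0], [0.0], []
    truth = []
    while t < params.duration:
        tau = params.tau_forward if direction > 0 else params.tau_backward
        d = rng.exponential(tau)
        truth.append(RunSegment("forward" if direction > 0 else "backward",
                                start_s=t, duration_s=d,
                                displacement_um=direction * params.speed * d,
                                censored=t + d > params.duration))
        t += d
        x += direction * params.speed * d
        switch_t.append(t)
        switch_x.append(x)
        dirs.append(direction)
        if params.bias_logistic is not None:
            p_fwd = logistic_bias(d, *params.bias_logistic)
            direction = 1 if rng.random() < p_fwd else -1
        else:
            direction = -direction
    times = np.arange(0.0, params.duration + 1e-9, params.frame_interval)
    pos = np.interp(times, switch_t, switch_x)
    if params.noise_sd > 0:
        pos = pos + rng.normal(0.0, params.noise_sd, len(pos))
    return Track(track_id, times, pos, meta={"seed": seed}), truth


def logistic_bias(duration_s: float, b0: float = 0.5, b1: float = 0.9,
                  t0: float = 1.0) -> float:
    """Forward-continuation probability rising with run duration."""
    return b0 + (b1 - b0) / (1.0 + math.exp(-(duration_s - t0)))


def gen_brownian_track(D: float, dimension: int = 2,
                       frame_interval: float = 0.1, n_frames: int = 600,
                       seed: int = 0, track_id: str = "bead") -> Track:
    """Pure Brownian track: Gaussian increments, variance 2 D dt per axis."""
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    sd = math.sqrt(2 * D * frame_interval)
    steps = rng.normal(0.0, sd, (n_frames - 1, dimension)) if D > 0 \
        else np.zeros((n_frames - 1, dimension))
    pos = np.vstack([np.zeros(dimension), np.cumsum(steps, axis=0)])
    times = np.arange(n_frames) * frame_interval
    y = pos[:, 1] if dimension == 2 else None
    return Track(track_id, times, pos[:, 0], y,
                 meta={"D_true": D, "seed": seed})


def gen_angle_trace(EI_true: float, L_hook: float = 60e-9,
                    temperature: float = 298.0, relaxation_s: float = 0.02,
                    n: int = 100_000, dt: float = 0.005,
                    seed: int = 0) -> AngleTrace:
    """Ornstein-Uhlenbeck orientation-angle trace.

    Stationary variance is k_B T L_hook / EI_true (equipartition inverted),
    relaxing with the given time constant; sampled exactly via the discrete
    OU update.  EI_true -> infinity gives a rigid (zero-variance) limit.
    """
    if relaxation_s <= dt:
        raise ValueError("relaxation time must exceed the sampling interval")
    var = K_B * temperature * L_hook / EI_true
    rng = np.random.default_rng(seed)
    rho = math.exp(-dt / relaxation_s)
    innov_sd = math.sqrt(var * (1 - rho**2))
    from scipy.signal import lfilter
    x0 = rng.normal(0.0, math.sqrt(var))
    noise = rng.normal(0.0, innov_sd, n - 1)
    # AR(1) recursion ang[i] = rho*ang[i-1] + noise[i-1]
    ang = np.concatenate([[x0], lfilter([1.0], [1.0, -rho], noise,
                                        zi=np.array([rho * x0]))[0]])
    return AngleTrace(np.arange(n) * dt, ang)


# --------------------------------------------------------------------------
# species cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortArchetype:
    """Species archetype for quasi-1D behavior: net-displacement band
    (um/min) and free-swimming speed band (um/s)."""

    label: str
    displacement_band: tuple = (40.0, 130.0)
    speed_band: tuple = (15.0, 34.0)


ARCHETYPES = {
    "wrapper": CohortArchetype("wrapper", (40.0, 130.0), (15.0, 34.0)),
    "nonwrapper": CohortArchetype("nonwrapper", (0.0, 6.0), (15.0, 34.0)),
}


def gen_species_cohort(archetype: CohortArchetype | str, n_cells: int = 20,
                       seed: int = 0, duration: float = 60.0,
                       max_attempts: int = 200) -> tuple[list[Track], dict]:
    """Generate a cohort of quasi-1D tracks for a species archetype.

    Wrapper cells are persistent run-and-reverse swimmers with a rising
    forward bias; non-wrapper cells switch back symmetrically on a short
    time scale and accumulate almost no net displacement.  Each track is
    rejection-checked through the pipeline's net-displacement measure until
    it falls in the archetype band.  Returns the tracks and a manifest with
    the ground-truth parameters per cell.
    """
    from .trajectory import net_displacement_per_minute
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    lo, hi = archetype.displacement_band
    rng = np.random.default_rng(seed)
    tracks, manifest = [], {"archetype": archetype.label, "seed": seed,
                            "cells": []}
    for c in range(n_cells):
        ok = False
        for attempt in range(max_attempts):
            sub = int(rng.integers(0, 2**31 - 1))
            if archetype.label == "wrapper":
                v = rng.uniform(0.8, 1.8)           # 3-10% of chamber speed
                p = RunReverseParams(
                    speed=v, tau_forward=rng.uniform(0.7, 1.2),
                    tau_backward=rng.uniform(0.3, 0.6), duration=duration,
                    bias_logistic=(0.5, 0.9, 1.0))
            else:
                v = rng.uniform(0.05, 0.25)
                p = RunReverseParams(
                    speed=v, tau_forward=0.5, tau_backward=0.5,
                    duration=duration, bias_logistic=None)
            tr, _ = gen_run_reverse_track(p, seed=sub,
                                          track_id=f"{archetype.label}_{c}")
            nd = net_displacement_per_minute(tr)
            if lo <= nd <= hi:
                ok = True
                manifest["cells"].append({
                    "track_id": tr.track_id, "seed": sub,
                    "speed_um_per_s": p.speed,
                    "tau_forward_s": p.tau_forward,
                    "tau_backward_s": p.tau_backward,
                    "net_displacement_um_per_min": nd,
                    "attempts": attempt + 1,
                })
                tracks.append(tr)
                break
        if not ok:
            raise RuntimeError(
                f"infeasible band {archetype.displacement_band} for "
                f"archetype {archetype.label!r}")
    return tracks, manifest
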