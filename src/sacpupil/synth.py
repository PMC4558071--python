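"""Synthetic eye-tracking experiments with the structure the analysis assumes.

The generator emulates a two-part session: a peak-velocity calibration part
(per-direction peak-velocity draws) and a main part of 17-degree saccades in
four directions over a flickering-grating background, in two conditions
(grating perpendicular vs parallel to the saccade).  It reproduces the
features the analysis is sensitive to:

* main-sequence-plausible peak velocities (~400 deg/s for 17 deg), more
  variable for vertical than horizontal saccades;
* saccade curvature (orthogonal velocity), larger for vertical saccades;
* a pupil trace with pre-saccadic dilation, a post-saccadic constriction
  from ~220 ms after the mid-saccade point, and an *extra* constriction in
  the intrasaccadic-percept condition from ~300 ms after it;
* blinks (masked gaps), white measurement noise, and a gaze-angle artifact
  in measured pupil area.

Percept strength is kinematic, not just a condition label: the extra
constriction scales with how well the trial's peak velocity matches the
grating's motion speed (peak-velocity error), and the parallel-grating
condition leaks a small percept when saccade curvature partially stabilizes
the grating.  This is what makes the direction post-hocs reproducible in
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .eye_signal import (DIRECTIONS, GazeTrace, axis_of)
from .io import Trial, TrialMeta
from .stimulus import ideal_spatial_frequency, orientation_for
from .trial_filter import part1_peak_validity

VIOLATIONS = ("anticipation", "late", "peak_undeterminable", "peak_too_high",
              "pre_deviation", "post_deviation")


@dataclass
class SimConfig:
    """All simulator knobs; a seed fixes the entire dataset.

    Amplitudes of pupil components are in ratio units (fraction of the
    trial's baseline area).  Velocity SDs are per-trial within participant;
    ``participant_v_sd`` jitters each participant x direction mean.
    """

    n_participants: int = 10
    n_trials_per_cell: int = 50          # per direction x condition
    part1_trials: int = 40               # valid trials behind each median
    amplitude_deg: float = 17.0
    eccentricity_deg: float = 8.5
    cue_onset_ms: int = 1000
    trial_after_cue_ms: int = 3000
    latency_mean_ms: float = 150.0
    latency_sd_ms: float = 30.0
    peak_v_mean: float = 400.0
    peak_v_sd_horizontal: float = 80.0
    peak_v_sd_vertical: float = 130.0
    participant_v_sd: float = 40.0
    curvature_mean_horizontal: float = 40.0
    curvature_sd_horizontal: float = 20.0
    curvature_mean_vertical: float = 110.0
    curvature_sd_vertical: float = 30.0
    gaze_noise_deg: float = 0.02
    pupil_baseline_mean: float = 1200.0
    pupil_baseline_sd: float = 150.0
    dilation_amp: float = 0.04
    dilation_tmax_ms: float = 350.0
    constriction_amp: float = 0.12
    constriction_onset_ms: float = 220.0   # after the mid-saccade point
    constriction_tmax_ms: float = 600.0
    condition_effect: float = 0.04         # extra constriction, ratio units
    condition_onset_ms: float = 300.0      # after the mid-saccade point
    condition_tmax_ms: float = 500.0
    effect_participant_sd: float = 0.3     # multiplicative scale across participants
    amp_jitter_cv: float = 0.15            # per-trial amplitude jitter
    velocity_tolerance: float = 150.0      # deg/s; width of the percept-strength falloff
    kernel_shape: float = 3.0
    blink_rate: float = 0.1                # blinks per trial
    blink_dur_mean_ms: float = 120.0
    blink_dur_sd_ms: float = 40.0
    noise_sd: float = 10.0                 # a.u. per 1-ms sample
    artifact_slope_x: float = 2.0          # a.u. per degree
    artifact_slope_y: float = 3.0
    frame_rate: float = 150.0
    seed: int = 0


def pupil_kernel(t_ms: np.ndarray, tmax_ms: float, shape: float = 3.0
                 ) -> np.ndarray:
    """Smooth unimodal impulse response, peak 1 at ``tmax_ms``; 0 for t<=0.

    Erlang-family kernel w(t) = (t/tmax)^n exp(n (1 - t/tmax)).  Larger n
    gives a narrower response.
    """
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / tmax_ms
    out[pos] = r ** shape * np.exp(shape * (1.0 - r))
    return out


def _direction_vectors(direction: str) -> Tuple[np.ndarray, np.ndarray]:
    """(along, orthogonal) unit vectors for a saccade direction."""
    along = {"left": (-1.0, 0.0), "right": (1.0, 0.0),
             "up": (0.0, 1.0), "down": (0.0, -1.0)}[direction]
    orth = (0.0, 1.0) if along[1] == 0.0 else (1.0, 0.0)
    return np.array(along), np.array(orth)


def simulate_saccade(
    amplitude: float,
    direction: str,
    peak_velocity: float,
    curvature: float = 0.0,
    onset_ms: int = 0,
) -> GazeTrace:
    """Kinematic saccade segment sampled at 1 kHz.

    The along-axis velocity is a raised-cosine pulse v(tau) =
    (Vp/2)(1 - cos 2 pi tau) whose duration D = 2 A / Vp makes the integral
    equal the amplitude and the maximum equal ``peak_velocity``.  The
    orthogonal component is a zero-integral biphasic sin(2 pi tau) pulse
    with peak ``curvature``, so the eye returns to the saccade axis by
    landing.  Positions are analytic integrals, not numeric cumsums.

    Returns a GazeTrace whose x/y are *displacements* from the starting
    point; the pupil channel is zero.
    """
    if amplitude <= 0 or peak_velocity <= 0:
        raise ValueError("amplitude and peak_velocity must be > 0")
    dur_ms = 2000.0 * amplitude / peak_velocity
    if dur_ms < 10.0:
        raise ValueError(
            f"implausible kinematics: duration {dur_ms:.1f} ms < 10 ms")
    n = int(np.ceil(dur_ms)) + 1
    t = np.arange(n, dtype=float)
    tau = np.clip(t / dur_ms, 0.0, 1.0)
    # analytic position integrals of the velocity pulses
    along = 0.5 * peak_velocity * (t / 1000.0
                                   - (dur_ms / 1000.0)
                                   * np.sin(2 * np.pi * tau) / (2 * np.pi))
    along = np.minimum(along, amplitude)
    orth = (curvature * (dur_ms / 1000.0) / (2 * np.pi)
            * (1.0 - np.cos(2 * np.pi * tau)))
    u, w = _direction_vectors(direction)
    x = along * u[0] + orth * w[0]
    y = along * u[1] + orth * w[1]
    return GazeTrace(t=onset_ms + np.arange(n), x=x, y=y,
                     pupil=np.zeros(n))


def simulate_pupil(
    t: np.ndarray,
    cue_onset_ms: float,
    mid_saccade_ms: float,
    baseline: float,
    cond_amp: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    dilation_amp: Optional[float] = None,
    constriction_amp: Optional[float] = None,
    gaze_x: Optional[np.ndarray] = None,
    gaze_y: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Pupil-area series (a.u.) for one trial.

    baseline * (1 + dilation - constriction - condition term) + position
    artifact + white noise.  Dilation (motor preparation) is locked to the
    cue; the post-saccadic constriction and the condition-specific extra
    constriction are impulses at mid-saccade + onset convolved with the
    response kernel.  ``cond_amp`` is the trial's percept-driven extra
    constriction amplitude (ratio units; 0 for a null trial).
    """
    t = np.asarray(t, dtype=float)
    dil = cfg.dilation_amp if dilation_amp is None else dilation_amp
    con = cfg.constriction_amp if constriction_amp is None else constriction_amp
    rel = (dil * pupil_kernel(t - cue_onset_ms, cfg.dilation_tmax_ms,
                              cfg.kernel_shape)
           - con * pupil_kernel(t - mid_saccade_ms - cfg.constriction_onset_ms,
                                cfg.constriction_tmax_ms, cfg.kernel_shape)
           - cond_amp * pupil_kernel(t - mid_saccade_ms - cfg.condition_onset_ms,
                                     cfg.condition_tmax_ms, cfg.kernel_shape))
    p = baseline * (1.0 + rel)
    if gaze_x is not None:
        p = p + cfg.artifact_slope_x * np.asarray(gaze_x)
    if gaze_y is not None:
        p = p + cfg.artifact_slope_y * np.asarray(gaze_y)
    if cfg.noise_sd > 0:
        p = p + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return p


def _jitter(rng: np.random.Generator, cv: float) -> float:
    return float(np.clip(rng.normal(1.0, cv), 0.0, None)) if cv > 0 else 1.0


def simulate_trial(
    participant: str,
    trial_id: int,
    direction: str,
    condition: str,
    peak_velocity: float,
    curvature: float,
    latency_ms: float,
    baseline: float,
    cond_amp: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    spatial_frequency: Optional[float] = None,
    violation: Optional[str] = None,
) -> Trial:
    """Assemble one full trial (gaze + pupil + metadata).

    ``violation`` plants exactly one exclusion-rule breach for filter tests:
    'anticipation', 'late', 'peak_undeterminable', 'peak_too_high',
    'pre_deviation' or 'post_deviation'.
    """
    if violation is not None and violation not in VIOLATIONS:
        raise ValueError(f"unknown violation {violation!r}")
    if violation == "anticipation":
        latency_ms = -50.0
    elif violation == "late":
        latency_ms = 2100.0
    elif violation == "peak_too_high":
        peak_velocity = 1100.0

    cue = cfg.cue_onset_ms
    n = cue + cfg.trial_after_cue_ms + 1
    t = np.arange(n)
    ecc = cfg.eccentricity_deg
    u, w = _direction_vectors(direction)
    fixation = (float(-ecc * u[0]), float(-ecc * u[1]))
    target = (float(ecc * u[0]), float(ecc * u[1]))

    x = np.full(n, fixation[0])
    y = np.full(n, fixation[1])
    sac = simulate_saccade(cfg.amplitude_deg, direction, peak_velocity,
                           curvature, onset_ms=int(round(cue + latency_ms)))
    i0 = int(sac.t[0])
    i1 = min(int(sac.t[-1]), n - 1)
    seg = slice(i0, i1 + 1)
    x[seg] = fixation[0] + sac.x[: i1 - i0 + 1]
    y[seg] = fixation[1] + sac.y[: i1 - i0 + 1]
    if i1 + 1 < n:
        x[i1 + 1:] = target[0]
        y[i1 + 1:] = target[1]
    true_mid = cue + latency_ms + 1000.0 * cfg.amplitude_deg / peak_velocity

    if violation == "pre_deviation":
        _add_bump(x, y, w, center=cue - 400, half_ms=100, amp=4.0)
    elif violation == "post_deviation":
        _add_bump(x, y, w, center=int(true_mid) + 500, half_ms=100, amp=4.0)

    if cfg.gaze_noise_deg > 0:
        x = x + rng.normal(0.0, cfg.gaze_noise_deg, size=n)
        y = y + rng.normal(0.0, cfg.gaze_noise_deg, size=n)

    pupil = simulate_pupil(
        t, cue, true_mid, baseline, cond_amp, cfg, rng,
        dilation_amp=cfg.dilation_amp * _jitter(rng, cfg.amp_jitter_cv),
        constriction_amp=cfg.constriction_amp * _jitter(rng, cfg.amp_jitter_cv),
        gaze_x=x, gaze_y=y,
    )

    valid = np.ones(n, dtype=bool)
    if cfg.blink_rate > 0 and rng.random() < cfg.blink_rate:
        dur = int(np.clip(rng.normal(cfg.blink_dur_mean_ms,
                                     cfg.blink_dur_sd_ms), 40, 400))
        start = int(rng.uniform(cue - 400, min(true_mid + 1000, n - dur - 1)))
        valid[start:start + dur] = False
        pupil[start:start + dur] = np.nan
    if violation == "peak_undeterminable":
        valid[:] = False
        pupil[:] = np.nan

    meta = TrialMeta(participant=participant, trial_id=trial_id,
                     direction=direction, condition=condition,
                     cue_onset=float(cue), fixation_pos=fixation,
                     target_pos=target, spatial_frequency=spatial_frequency)
    return Trial(meta=meta,
                 trace=GazeTrace(t=t, x=x, y=y, pupil=pupil, valid=valid))


def _add_bump(x, y, w, center: int, half_ms: int, amp: float) -> None:
    """Out-and-back gaze excursion of ``amp`` degrees along unit vector w."""
    n = len(x)
    t0, t1 = center - half_ms, center + half_ms
    if t0 < 0 or t1 >= n:
        raise ValueError("bump does not fit in the trial")
    tau = np.linspace(0.0, 1.0, t1 - t0 + 1)
    bump = amp * 0.5 * (1.0 - np.cos(2 * np.pi * tau))
    x[t0:t1 + 1] += bump * w[0]
    y[t0:t1 + 1] += bump * w[1]


@dataclass
class SimDataset:
    """A complete synthetic experiment plus its ground truth."""

    trials: List[Trial]
    part1_peaks: Dict[Tuple[str, str], np.ndarray]   # (participant, direction)
    optimal_velocity: Dict[Tuple[str, str], float]
    spatial_frequency: Dict[Tuple[str, str], float]
    truth: pd.DataFrame                              # per-trial ground truth
    config: SimConfig


def _axis_params(cfg: SimConfig, direction: str):
    if axis_of(direction) == "horizontal":
        return (cfg.peak_v_sd_horizontal, cfg.curvature_mean_horizontal,
                cfg.curvature_sd_horizontal)
    return (cfg.peak_v_sd_vertical, cfg.curvature_mean_vertical,
            cfg.curvature_sd_vertical)


def simulate_experiment(cfg: SimConfig) -> SimDataset:
    """Generate the full factorial experiment deterministically from the seed.

    Per participant and direction: the calibration part draws peak
    velocities until ``part1_trials`` of them fall in the plausibility band;
    their median is the direction's optimal velocity, and the grating
    spatial frequency follows from the half-cycle-per-frame rule.  Main-part
    trials then draw their own kinematics, and the percept-driven extra
    constriction amplitude is computed from the trial's peak-velocity error
    (percept condition) or orthogonal peak velocity (no-percept condition)
    through a Gaussian falloff of width ``velocity_tolerance``.
    """
    rng = np.random.default_rng(cfg.seed)
    trials: List[Trial] = []
    part1: Dict[Tuple[str, str], np.ndarray] = {}
    optimal: Dict[Tuple[str, str], float] = {}
    sfreq: Dict[Tuple[str, str], float] = {}
    truth_rows = []
    trial_id = 0

    for ip in range(cfg.n_participants):
        pid = f"p{ip:02d}"
        baseline = float(np.clip(
            rng.normal(cfg.pupil_baseline_mean, cfg.pupil_baseline_sd),
            400.0, None))
        effect_scale = float(np.clip(
            rng.normal(1.0, cfg.effect_participant_sd), 0.2, None))
        dir_means = {
            d: cfg.peak_v_mean + rng.normal(0.0, cfg.participant_v_sd)
            for d in DIRECTIONS
        }
        for direction in DIRECTIONS:
            v_sd, c_mean, c_sd = _axis_params(cfg, direction)
            draws: List[float] = []
            n_valid = 0
            while n_valid < cfg.part1_trials and len(draws) < 50 * cfg.part1_trials:
                v = float(np.clip(rng.normal(dir_means[direction], v_sd),
                                  50.0, None))
                draws.append(v)
                if part1_peak_validity(v):
                    n_valid += 1
            peaks = np.array(draws)
            part1[(pid, direction)] = peaks
            valid = peaks[[part1_peak_validity(v) for v in peaks]]
            opt = float(np.median(valid[: cfg.part1_trials]))
            optimal[(pid, direction)] = opt
            sf = ideal_spatial_frequency(opt, cfg.frame_rate)
            sfreq[(pid, direction)] = sf

            for condition in ("no_percept", "intrasaccadic_percept"):
                for _ in range(cfg.n_trials_per_cell):
                    peak_v = float(np.clip(
                        rng.normal(dir_means[direction], v_sd), 150.0, None))
                    curv = float(np.clip(rng.normal(c_mean, c_sd), 0.0, None))
                    latency = float(np.clip(
                        rng.normal(cfg.latency_mean_ms, cfg.latency_sd_ms),
                        10.0, None))
                    if condition == "intrasaccadic_percept":
                        mismatch = peak_v - opt
                    else:
                        mismatch = curv - opt
                    factor = float(np.exp(-(mismatch / cfg.velocity_tolerance) ** 2))
                    cond_amp = (cfg.condition_effect * effect_scale
                                * _jitter(rng, cfg.amp_jitter_cv) * factor)
                    trial = simulate_trial(
                        pid, trial_id, direction, condition, peak_v, curv,
                        latency, baseline, cond_amp, cfg, rng,
                        spatial_frequency=sf)
                    trials.append(trial)
                    truth_rows.append({
                        "trial": trial_id, "participant": pid,
                        "direction": direction, "condition": condition,
                        "peak_velocity": peak_v, "curvature": curv,
                        "latency_ms": latency, "cond_amp": cond_amp,
                        "optimal_velocity": opt,
                        "peak_velocity_error": abs(peak_v - opt),
                    })
                    trial_id += 1
    return SimDataset(trials=trials, part1_peaks=part1,
                      optimal_velocity=optimal, spatial_frequency=sfreq,
                      truth=pd.DataFrame(truth_rows), config=cfg)
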