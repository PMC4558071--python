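"""Stage composition: raw trials -> epochs -> exclusion -> sweep -> profiles.

The pipeline mirrors the order of the original analysis: smooth eye
position, estimate velocities, find the mid-saccade point, reconstruct
blinks, apply the exclusion rules, epoch and normalize the kept trials, and
run the sample-wise mixed-model sweep.  Everything is deterministic given
the inputs, the config and the seed, and :func:`run_pipeline` writes a
manifest with content hashes so two runs can be compared at a glance.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as sio
from .config import RunConfig
from .eye_signal import (SaccadeError, SaccadeEvent, compute_velocity,
                         detect_saccade, smooth_position)
from .pupil_signal import (EpochRejected, EpochedPupil, epoch_and_normalize,
                           reconstruct_blinks)
from .retinal import StabilizationProfile, stabilization_profile
from .stats import SweepResult, lme_sweep
from .stimulus import GratingStimulus, orientation_for
from .trial_filter import ExclusionReport, apply_part2_filter
from .synth import SimConfig, simulate_experiment


@dataclass
class PreprocessedTrial:
    trial: sio.Trial
    event: Optional[SaccadeEvent]
    vx: Optional[np.ndarray] = None
    vy: Optional[np.ndarray] = None
    epoch: Optional[EpochedPupil] = None
    epoch_rejection: Optional[str] = None


@dataclass
class PipelineResult:
    preprocessed: List[PreprocessedTrial]
    report: ExclusionReport
    epochs: List[EpochedPupil]
    sweep: Optional[SweepResult]
    profiles: Dict[int, StabilizationProfile]
    config: RunConfig


def preprocess_trial(trial: sio.Trial, cfg: RunConfig) -> PreprocessedTrial:
    """Kinematics and epoching for a single trial.

    A trial with no detectable saccade gets ``event=None`` (the exclusion
    rules turn that into peak_undeterminable); a trial whose baseline window
    is unusable gets an ``epoch_rejection`` reason instead of an epoch.
    """
    smoothed = smooth_position(trial.trace, cfg.smoothing_window_ms)
    vx, vy = compute_velocity(smoothed)
    try:
        event = detect_saccade(smoothed, trial.meta, vx, vy,
                               onset_threshold=cfg.onset_threshold,
                               peak_mode=cfg.peak_mode)
    except SaccadeError:
        return PreprocessedTrial(trial=trial, event=None, vx=vx, vy=vy)

    repaired = reconstruct_blinks(trial.trace, cfg.blink_margin_ms,
                                  cfg.max_blink_ms)
    try:
        epoch = epoch_and_normalize(
            repaired, event.mid_saccade_t, cfg.epoch_window_ms,
            cfg.baseline_window_ms, cfg.normalization, meta=trial.meta)
        return PreprocessedTrial(trial=trial, event=event, vx=vx, vy=vy,
                                 epoch=epoch)
    except EpochRejected as exc:
        return PreprocessedTrial(trial=trial, event=event, vx=vx, vy=vy,
                                 epoch_rejection=str(exc))


def preprocess(trials: Sequence[sio.Trial], cfg: RunConfig
               ) -> List[PreprocessedTrial]:
    return [preprocess_trial(t, cfg) for t in trials]


def trial_profile(pre: PreprocessedTrial, cfg: RunConfig
                  ) -> Optional[StabilizationProfile]:
    """Retinal stabilization profile of one preprocessed trial's grating."""
    meta = pre.trial.meta
    if meta.spatial_frequency is None or pre.vx is None:
        return None
    stim = GratingStimulus(
        orientation=orientation_for(meta.direction, meta.condition),
        spatial_frequency=meta.spatial_frequency,
        frame_rate=cfg.frame_rate)
    return stabilization_profile(pre.trial.trace.t, pre.vx, pre.vy, stim,
                                 theta=cfg.theta_stabilization)


def run_pipeline(
    trials: Optional[Sequence[sio.Trial]] = None,
    cfg: RunConfig = RunConfig(),
    sim_config: Optional[SimConfig] = None,
    model: Optional[str] = "condition*direction",
    out_dir: Optional[str] = None,
    with_profiles: bool = False,
) -> PipelineResult:
    """Run every stage on raw trials (or a freshly simulated experiment).

    When ``out_dir`` is given, writes epochs.csv, exclusions.csv/.json,
    sweep.json and manifest.json (content hashes + resolved config).
    ``model=None`` skips the statistical sweep (preprocessing and filtering
    only).
    """
    if trials is None:
        if sim_config is None:
            raise ValueError("provide trials or a sim_config")
        trials = simulate_experiment(sim_config).trials
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")

    pres = preprocess(trials, cfg)
    report = apply_part2_filter(trials, [p.event for p in pres], cfg)
    epochs = [p.epoch for p, keep in zip(pres, report.kept)
              if keep and p.epoch is not None]
    sweep = None
    if epochs and model is not None:
        df = sio.epochs_to_frame(epochs)
        values, times, factors = sio.frame_to_matrix(df, decimate=cfg.decimate)
        sweep = lme_sweep(values, times, factors, model=model,
                          threshold=cfg.t_threshold,
                          min_run_ms=cfg.min_run_ms,
                          two_sided=cfg.two_sided, reml=cfg.reml)
    profiles: Dict[int, StabilizationProfile] = {}
    if with_profiles:
        for p, keep in zip(pres, report.kept):
            if keep:
                prof = trial_profile(p, cfg)
                if prof is not None:
                    profiles[p.trial.meta.trial_id] = prof

    result = PipelineResult(preprocessed=pres, report=report, epochs=epochs,
                            sweep=sweep, profiles=profiles, config=cfg)
    if out_dir is not None:
        _write_outputs(result, out_dir, sim_config)
    return result


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(result: PipelineResult, out_dir: str,
                   sim_config: Optional[SimConfig]) -> None:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    ep_path = os.path.join(out_dir, "epochs.csv")
    sio.write_epochs(result.epochs, ep_path)
    paths["epochs.csv"] = ep_path
    ex_csv = os.path.join(out_dir, "exclusions.csv")
    result.report.write_csv(ex_csv)
    paths["exclusions.csv"] = ex_csv
    ex_json = os.path.join(out_dir, "exclusions.json")
    result.report.write_json(ex_json)
    paths["exclusions.json"] = ex_json
    if result.sweep is not None:
        sw_path = os.path.join(out_dir, "sweep.json")
        with open(sw_path, "w", encoding="utf-8") as fh:
            fh.write(result.sweep.to_json())
        paths["sweep.json"] = sw_path
    manifest = {
        "config": result.config.to_dict(),
        "sim_config": None if sim_config is None else vars(sim_config),
        "files": {name: _sha256(path) for name, path in paths.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def trial_metrics(pres: Sequence[PreprocessedTrial], cfg: RunConfig
                  ) -> pd.DataFrame:
    """Per-trial kinematic metrics for the post-hoc trial selections.

    The optimal peak velocity is recovered from each trial's grating: the
    spatial frequency was set so the grating's motion speed equals the
    calibrated peak velocity, so optimal = frame_rate / (2 * SF).
    """
    from .retinal import peak_velocity_error
    rows = []
    for p in pres:
        m, e = p.trial.meta, p.event
        if e is None or m is None or m.spatial_frequency is None:
            continue
        if not np.isfinite(e.peak_velocity):
            continue
        optimal = cfg.frame_rate / (2.0 * m.spatial_frequency)
        rows.append({
            "trial": m.trial_id, "participant": m.participant,
            "direction": m.direction, "condition": m.condition,
            "axis": e.axis,
            "peak_velocity": e.peak_velocity,
            "peak_orthogonal_velocity": e.peak_orthogonal_velocity,
            "optimal_velocity": optimal,
            "peak_velocity_error": peak_velocity_error(e.peak_velocity,
                                                       optimal),
        })
    return pd.DataFrame(rows)


def sweep_epochs(epochs: Sequence[EpochedPupil], cfg: RunConfig,
                 model: str = "condition") -> SweepResult:
    """Run the mixed-model sweep over a (sub)set of epochs."""
    df = sio.epochs_to_frame(epochs)
    values, times, factors = sio.frame_to_matrix(df, decimate=cfg.decimate)
    return lme_sweep(values, times, factors, model=model,
                     threshold=cfg.t_threshold, min_run_ms=cfg.min_run_ms,
                     two_sided=cfg.two_sided, reml=cfg.reml)


# ---------------------------------------------------------------------------
# Replicate studies (parameter recovery / false-positive rate)
# ---------------------------------------------------------------------------

def recovery_replicates(
    sim_config: SimConfig,
    cfg: RunConfig,
    n_replicates: int,
    seed: int,
    model: str = "condition*direction",
    effect: str = "condition[percept]",
) -> pd.DataFrame:
    """Run the full pipeline on seeded replicates; summarize the target effect.

    Each replicate simulates a fresh experiment (seed derived from ``seed``),
    runs preprocessing, exclusion and the sweep, and records whether a
    reliable *negative* interval for ``effect`` intersects the window after
    the injected effect's onset.
    """
    rows = []
    onset = sim_config.condition_onset_ms
    end = cfg.epoch_window_ms[1]
    for r in range(n_replicates):
        sc = SimConfig(**{**vars(sim_config), "seed": (seed * 1000 + r) % (2**31)})
        res = run_pipeline(sim_config=sc, cfg=cfg, model=model)
        sweep = res.sweep
        intervals = sweep.intervals.get(effect, [])
        i_eff = sweep.effect_names.index(effect)
        hits = []
        for (a, b) in intervals:
            inside = (sweep.times >= a) & (sweep.times < b)
            mean_coef = float(np.nanmean(sweep.coef[inside, i_eff]))
            if mean_coef < 0 and b > onset and a < end:
                hits.append((a, b))
        rows.append({
            "replicate": r, "seed": sc.seed,
            "n_intervals": len(intervals),
            "recovered": bool(hits),
            "first_start_ms": hits[0][0] if hits else np.nan,
            "first_end_ms": hits[0][1] if hits else np.nan,
            "retention": res.report.retention,
        })
    return pd.DataFrame(rows)
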