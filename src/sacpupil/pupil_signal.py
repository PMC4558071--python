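"""Pupil-signal processing: blink reconstruction, epoching, normalization.

Pupil size is analysed as *area* in the tracker's arbitrary units, expressed
relative to a pre-saccadic baseline.  The pupil trace is deliberately never
smoothed; only blinks are repaired, by cubic-spline interpolation across the
gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .eye_signal import GazeTrace


class EpochRejected(ValueError):
    """Raised when an epoch cannot be formed (e.g. fully-masked baseline)."""


@dataclass
class EpochedPupil:
    """Baseline-normalized pupil time course locked to the mid-saccade point.

    ``rel_t`` runs from -300 to +1200 ms in 1-ms steps (1,501 samples).
    Under divisive normalization a value of 1.0 means "at baseline"; the
    baseline is the mean reconstructed pupil area from -105 to -95 ms.
    """

    rel_t: np.ndarray       # ms relative to mid-saccade point
    values: np.ndarray      # normalized pupil
    valid: np.ndarray       # bool mask
    baseline: float         # raw-area baseline (a.u.)
    meta: object = None     # TrialMeta of the source trial, if any


def _invalid_runs(valid: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open [start, stop) index runs of masked samples."""
    bad = ~np.asarray(valid, dtype=bool)
    if not bad.any():
        return []
    edges = np.diff(bad.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if bad[0]:
        starts.insert(0, 0)
    if bad[-1]:
        stops.append(len(bad))
    return list(zip(starts, stops))


def reconstruct_blinks(
    trace: GazeTrace,
    margin_ms: int = 50,
    max_blink_ms: int = 500,
) -> GazeTrace:
    """Repair blink gaps in the pupil channel by cubic-spline interpolation.

    Each run of masked samples is extended by ``margin_ms`` on both sides
    (the pupil signal is distorted just before and after a blink) and the
    extended run is replaced by a cubic spline through four anchor samples:
    at run-edge +/- margin and +/- 2*margin.  Runs whose anchors fall outside
    the trace or on masked samples (e.g. a blink at the very start), and runs
    longer than ``max_blink_ms``, are left masked.  Samples outside extended
    runs are never altered.
    """
    out = trace.copy()
    n = len(out)
    m = int(margin_ms)
    for start, stop in _invalid_runs(trace.valid):
        if (stop - start) > max_blink_ms:
            continue
        a0, a1 = start - 2 * m, start - m
        b0, b1 = stop - 1 + m, stop - 1 + 2 * m
        anchors = np.array([a0, a1, b0, b1])
        if anchors[0] < 0 or anchors[-1] >= n:
            continue
        if not trace.valid[anchors].all():
            continue
        spline = CubicSpline(out.t[anchors], out.pupil[anchors])
        lo, hi = a1 + 1, b0  # open interval between the inner anchors
        if lo >= hi:
            continue
        out.pupil[lo:hi] = spline(out.t[lo:hi])
        out.valid[lo:hi] = True
    return out


def epoch_and_normalize(
    trace: GazeTrace,
    mid_saccade_t: float,
    epoch_window_ms: Tuple[int, int] = (-300, 1200),
    baseline_window_ms: Tuple[int, int] = (-105, -95),
    normalization: str = "divisive",
    meta=None,
) -> EpochedPupil:
    """Cut a mid-saccade-locked epoch and normalize it to its baseline.

    The baseline is the mean pupil area over ``baseline_window_ms`` (valid
    samples only; at least one required, else the epoch is rejected with a
    reason).  ``divisive`` normalization divides by the baseline, so the
    epoch's baseline-window mean is exactly 1; ``subtractive`` subtracts it.
    Samples outside the trace's coverage are masked.  No smoothing is ever
    applied to the pupil channel.
    """
    lo, hi = epoch_window_ms
    rel_t = np.arange(lo, hi + 1)
    n = rel_t.size
    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)

    abs_t = rel_t + int(round(mid_saccade_t))
    inside = (abs_t >= trace.t[0]) & (abs_t <= trace.t[-1])
    idx = np.searchsorted(trace.t, abs_t[inside])
    values[inside] = trace.pupil[idx]
    valid[inside] = trace.valid[idx]

    blo, bhi = baseline_window_ms
    in_base = (rel_t >= blo) & (rel_t <= bhi)
    base_vals = values[in_base & valid]
    if base_vals.size == 0:
        raise EpochRejected(
            f"baseline window [{blo}, {bhi}] ms has no valid samples"
        )
    baseline = float(np.mean(base_vals))

    if normalization == "divisive":
        if baseline == 0:
            raise EpochRejected("zero baseline")
        values = values / baseline
    elif normalization == "subtractive":
        values = values - baseline
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    values[~valid] = np.nan
    return EpochedPupil(rel_t=rel_t, values=values, valid=valid,
                        baseline=baseline, meta=meta)


def fit_position_artifact(
    baselines: Sequence[float],
    positions: Sequence[Tuple[float, float]],
) -> Tuple[float, float, float]:
    """Linear fit of baseline pupil area on gaze position.

    Returns (intercept, slope_x, slope_y) of an ordinary least-squares fit
    of baseline area (a.u.) on horizontal and vertical gaze position (deg).
    Requires at least 3 trials at non-collinear positions.
    """
    pos = np.asarray(positions, dtype=float)
    base = np.asarray(baselines, dtype=float)
    if pos.shape[0] < 3:
        raise ValueError("need >= 3 trials to fit the position artifact")
    X = np.column_stack([np.ones(len(base)), pos[:, 0], pos[:, 1]])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("gaze positions are collinear; artifact fit is rank-deficient")
    coef, *_ = np.linalg.lstsq(X, base, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def remove_position_artifact(
    traces: Sequence[GazeTrace],
    baselines: Sequence[float],
    positions: Sequence[Tuple[float, float]],
) -> List[GazeTrace]:
    """Subtract the fitted gaze-position component from raw pupil traces.

    One fit per call (callers group by participant).  The fitted
    slope_x*x + slope_y*y component, evaluated at each trial's fixation
    position, is removed from the whole trace so that relative (normalized)
    pupil responses are unaffected by where on the screen the trial started.

    This correction is OFF by default in the pipeline: gaze angle has both a
    real and an artifactual effect on measured pupil area, with opposite
    signs, so regressing position out can over- or under-correct.
    """
    _, bx, by = fit_position_artifact(baselines, positions)
    out = []
    for trace, (px, py) in zip(traces, positions):
        corrected = trace.copy()
        corrected.pupil = corrected.pupil - (bx * px + by * py)
        out.append(corrected)
    return out
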