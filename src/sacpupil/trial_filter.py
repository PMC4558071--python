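"""Trial validity and exclusion rules, with per-rule bookkeeping.

Two kinds of rule live here.  The peak-velocity plausibility band
(220-664 deg/s for 17 deg saccades) governs which trials count toward the
per-direction median peak velocity used to calibrate the grating.  The
exclusion rules proper drop trials from the pupil analysis: anticipatory or
very late saccades, undeterminable or implausibly high peak velocity
(usually data loss), and gaze deviating from the fixation dot before — or the
saccade target after — the saccade.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .eye_signal import GazeTrace, SaccadeEvent

#: Exclusion reasons in the order they are checked; a trial records only the
#: first rule that fires.
REASONS = (
    "anticipation",
    "late",
    "peak_undeterminable",
    "peak_too_high",
    "pre_deviation",
    "post_deviation",
)


def part1_peak_validity(
    v: float, bounds: Tuple[float, float] = (220.0, 664.0)
) -> bool:
    """True iff a peak velocity is plausible for a 17-degree saccade.

    'Above'/'below' the band are read strictly, so the bounds themselves are
    valid.
    """
    lo, hi = bounds
    return bool(lo <= v <= hi)


def part1_peak_estimate(
    peaks: Sequence[float],
    n_required: int = 40,
    bounds: Tuple[float, float] = (220.0, 664.0),
) -> float:
    """Median of the plausible peak velocities for one direction.

    Raises if fewer than ``n_required`` trials survive the plausibility band,
    reporting the shortfall.
    """
    valid = [float(v) for v in peaks if part1_peak_validity(v, bounds)]
    if len(valid) < n_required:
        raise ValueError(
            f"only {len(valid)} valid trials, {n_required} required "
            f"(short by {n_required - len(valid)})"
        )
    return float(np.median(valid))


def part2_exclude(
    trace: GazeTrace,
    event: Optional[SaccadeEvent],
    meta,
    cfg: RunConfig = RunConfig(),
) -> Optional[str]:
    """First exclusion rule a trial violates, or None if it is kept.

    Rules, in order: latency < 0 ms (anticipation) or above the latency
    ceiling; peak velocity undeterminable (no saccade found or all samples
    masked); peak velocity above the data-loss ceiling; gaze farther than the
    deviation limit from the fixation dot before the saccade; ditto from the
    target after the saccade.  Both deviation checks ignore masked samples
    and a window of ``2 * exclusion_halfwindow_ms`` centered on the
    mid-saccade point.
    """
    if event is not None:
        if event.latency < 0:
            return "anticipation"
        if event.latency > cfg.max_latency_ms:
            return "late"
    if event is None or not np.isfinite(event.peak_velocity):
        return "peak_undeterminable"
    if event.peak_velocity > cfg.max_peak_velocity:
        return "peak_too_high"

    half = cfg.exclusion_halfwindow_ms
    mid = event.mid_saccade_t
    fx, fy = meta.fixation_pos
    tx, ty = meta.target_pos

    pre = (trace.t < mid - half) & trace.valid
    if pre.any():
        d = np.hypot(trace.x[pre] - fx, trace.y[pre] - fy)
        if np.max(d) > cfg.max_deviation_deg:
            return "pre_deviation"
    post = (trace.t > mid + half) & trace.valid
    if post.any():
        d = np.hypot(trace.x[post] - tx, trace.y[post] - ty)
        if np.max(d) > cfg.max_deviation_deg:
            return "post_deviation"
    return None


@dataclass
class ExclusionReport:
    """Keep/drop decision and first matching reason for every trial."""

    trial_ids: List = field(default_factory=list)
    reasons: List[Optional[str]] = field(default_factory=list)

    def add(self, trial_id, reason: Optional[str]) -> None:
        self.trial_ids.append(trial_id)
        self.reasons.append(reason)

    @property
    def kept(self) -> List[bool]:
        return [r is None for r in self.reasons]

    @property
    def n_total(self) -> int:
        return len(self.reasons)

    @property
    def n_kept(self) -> int:
        return sum(self.kept)

    @property
    def retention(self) -> float:
        """Fraction of trials kept."""
        if not self.reasons:
            return float("nan")
        return self.n_kept / self.n_total

    def counts(self) -> dict:
        return {r: self.reasons.count(r) for r in REASONS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial_ids,
                "keep": self.kept,
                "reason": ["" if r is None else r for r in self.reasons],
            }
        )

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "retention": self.retention,
            "counts": self.counts(),
        }

    def write_csv(self, sink: Union[str, IO[str]]) -> None:
        self.to_frame().to_csv(sink, index=False, lineterminator="\n")

    def write_json(self, sink: Union[str, IO[str]]) -> None:
        text = json.dumps(self.summary(), indent=2)
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)


def apply_part2_filter(
    trials: Sequence,
    events: Sequence[Optional[SaccadeEvent]],
    cfg: RunConfig = RunConfig(),
) -> ExclusionReport:
    """Run :func:`part2_exclude` over (trial, event) pairs.

    ``trials`` are objects with ``meta`` and ``trace`` attributes (see
    :mod:`sacpupil.io`).
    """
    report = ExclusionReport()
    for trial, event in zip(trials, events):
        reason = part2_exclude(trial.trace, event, trial.meta, cfg)
        report.add(trial.meta.trial_id, reason)
    return report
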