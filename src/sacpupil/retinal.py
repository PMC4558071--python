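"""Retinal stabilization of the flickering grating during a saccade.

For each of the grating's two motion interpretations the retinal speed is
the absolute difference between the interpretation's velocity and the eye
velocity along the motion axis.  The stabilization index s(t) is the smaller
of the two: the grating is (approximately) stabilized whenever *either*
reading of the ambiguous motion is cancelled by the eye movement.  The
predicted intrasaccadic-percept window is the maximal interval where s(t)
falls below a tolerance theta.

Geometry matters: a grating perpendicular to the saccade moves along the
saccade axis, so the along-axis eye velocity (which peaks at several hundred
deg/s) can cancel it.  A parallel grating moves orthogonally to the saccade;
only saccade curvature (orthogonal velocity) works against it, which at most
*partially* stabilizes the grating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .stimulus import GratingStimulus, MotionInterpretation, motion_interpretations


def retinal_speed(
    eye_velocity_component: float, interp: MotionInterpretation
) -> float:
    """Retinal speed (deg/s) of one motion interpretation.

    ``eye_velocity_component`` is the signed eye velocity along the
    interpretation's motion axis.
    """
    return float(np.abs(interp.speed * interp.sign - eye_velocity_component))


def peak_velocity_error(actual: float, optimal: float) -> float:
    """|actual - optimal| peak velocity (deg/s).

    The optimal peak velocity is the grating's motion speed; the farther the
    actual peak is from it, the worse the mid-saccade stabilization.  The
    signed difference is ``actual - optimal`` if the direction of the miss
    matters.
    """
    if actual <= 0 or optimal <= 0:
        raise ValueError("velocities must be positive")
    return float(abs(actual - optimal))


@dataclass
class StabilizationProfile:
    """Time course of retinal stabilization for one trial.

    ``s`` is the stabilization index (deg/s, >= 0).  ``percept_window`` is
    the maximal [start_ms, end_ms] interval with s < theta (earliest such
    run on ties), or None when s never drops below theta.
    """

    t: np.ndarray
    s: np.ndarray
    speed_pos: np.ndarray        # retinal speed of the +1 interpretation
    speed_neg: np.ndarray        # retinal speed of the -1 interpretation
    theta: float
    percept_window: Optional[Tuple[float, float]]

    @property
    def window_duration(self) -> float:
        if self.percept_window is None:
            return 0.0
        return self.percept_window[1] - self.percept_window[0]


def _longest_run_below(t: np.ndarray, s: np.ndarray, theta: float):
    below = s < theta
    if not below.any():
        return None
    edges = np.diff(below.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(len(below))
    best = max(zip(starts, stops), key=lambda r: (r[1] - r[0], -r[0]))
    return float(t[best[0]]), float(t[best[1] - 1])


def stabilization_profile(
    t: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    stim: GratingStimulus,
    theta: float = 50.0,
) -> StabilizationProfile:
    """Stabilization index over time for one trial and one grating.

    The eye-velocity component entering the index is selected by the
    grating's own motion axis: for percept geometry (grating perpendicular
    to the saccade) that is the along-saccade component, for no-percept
    geometry (parallel grating) it is the orthogonal component.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(vx if stim.motion_axis == "horizontal" else vy, dtype=float)
    pos, neg = motion_interpretations(stim)
    sp = np.abs(pos.velocity - v)
    sn = np.abs(neg.velocity - v)
    s = np.minimum(sp, sn)
    window = _longest_run_below(t, s, theta)
    return StabilizationProfile(
        t=t, s=s, speed_pos=sp, speed_neg=sn, theta=theta,
        percept_window=window,
    )
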