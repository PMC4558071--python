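"""Eye-position signal processing: smoothing, velocity, saccade landmarks.

All traces are uniformly sampled at 1 kHz, expressed in degrees from screen
center with y positive upward.  Saccade landmarks are time-locked to the
*mid-saccade point*: the moment the eyes cross the screen meridian orthogonal
to the saccade axis (the vertical meridian for horizontal saccades, the
horizontal meridian for vertical ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

HORIZONTAL_DIRECTIONS = ("left", "right")
VERTICAL_DIRECTIONS = ("up", "down")
DIRECTIONS = HORIZONTAL_DIRECTIONS + VERTICAL_DIRECTIONS


class SaccadeError(ValueError):
    """Raised when no saccade (meridian crossing) can be found in a trial."""


def axis_of(direction: str) -> str:
    """Saccade axis ('horizontal' or 'vertical') for a direction label."""
    if direction in HORIZONTAL_DIRECTIONS:
        return "horizontal"
    if direction in VERTICAL_DIRECTIONS:
        return "vertical"
    raise ValueError(f"unknown saccade direction {direction!r}")


@dataclass
class GazeTrace:
    """One trial's gaze and pupil samples on a gap-free 1-ms grid.

    ``valid`` marks usable samples; blinks and data loss are False.  Pupil
    area is in the tracker's arbitrary units.  A pupil value of 0 is a blink
    sentinel in raw files and is never present after ingestion — it becomes a
    masked sample instead.
    """

    t: np.ndarray          # int ms, strictly increasing, step 1
    x: np.ndarray          # deg, positive rightward
    y: np.ndarray          # deg, positive upward
    pupil: np.ndarray      # arbitrary units
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        for name in ("x", "y", "pupil", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match t")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "GazeTrace":
        return GazeTrace(self.t.copy(), self.x.copy(), self.y.copy(),
                         self.pupil.copy(), self.valid.copy())


@dataclass
class SaccadeEvent:
    """Kinematic landmarks of one saccade.

    ``latency`` is onset minus cue onset and may be negative (anticipatory
    saccade).  Peak velocities are taken over the whole trial, masked samples
    ignored.
    """

    onset: float                      # ms
    mid_saccade_t: float              # ms, meridian crossing on the 1-ms grid
    latency: float                    # ms
    peak_velocity: float              # deg/s
    peak_orthogonal_velocity: float   # deg/s
    axis: str                         # 'horizontal' | 'vertical'


def hanning_kernel(window_ms: int) -> np.ndarray:
    """Unit-sum Hanning window of ``window_ms`` samples at 1 kHz."""
    if window_ms < 3 or window_ms % 2 == 0:
        raise ValueError("window must be an odd number of samples >= 3")
    w = np.hanning(window_ms)
    return w / w.sum()


def smooth_position(trace: GazeTrace, window_ms: int = 11) -> GazeTrace:
    """Smooth x and y with a unit-sum Hanning window; edges by reflection.

    Length is preserved and a constant trace passes through unchanged.  The
    pupil channel is untouched (pupil size is deliberately not smoothed).
    """
    n = len(trace)
    if window_ms > n:
        raise ValueError(f"window ({window_ms}) longer than trace ({n})")
    w = hanning_kernel(window_ms)
    half = window_ms // 2

    def _smooth(v: np.ndarray) -> np.ndarray:
        padded = np.pad(v, half, mode="reflect")
        return np.convolve(padded, w, mode="valid")

    out = trace.copy()
    out.x = _smooth(trace.x)
    out.y = _smooth(trace.y)
    return out


def compute_velocity(trace: GazeTrace) -> Tuple[np.ndarray, np.ndarray]:
    """Per-axis eye velocity in deg/s by central finite differences.

    Interior samples use the symmetric two-sided difference; the endpoints
    use one-sided differences.  Requires a uniform 1-ms grid.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples for velocity")
    dt = np.diff(trace.t)
    if np.any(dt != dt[0]):
        raise ValueError("non-uniform sampling; resample before velocity")
    dt_s = dt[0] / 1000.0
    vx = np.gradient(trace.x, dt_s)
    vy = np.gradient(trace.y, dt_s)
    return vx, vy


def peak_velocity(
    vx: np.ndarray,
    vy: np.ndarray,
    valid: Optional[np.ndarray] = None,
    mode: str = "component",
) -> Optional[float]:
    """Peak eye speed over the whole trial, or None if undeterminable.

    'component' mode takes the maximum over time of max(|vx|, |vy|) — the
    highest single-axis speed at any moment.  'vector' mode uses the
    Euclidean speed.  All-masked trials yield None (undeterminable) rather
    than a number.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if valid is None:
        valid = np.ones(vx.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        return None
    if mode == "component":
        speed = np.maximum(np.abs(vx), np.abs(vy))
    elif mode == "vector":
        speed = np.hypot(vx, vy)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.max(speed[valid]))


def orthogonal_velocity(
    vx: np.ndarray,
    vy: np.ndarray,
    axis: str,
    valid: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Peak |velocity| perpendicular to the saccade axis (saccade curvature).

    Horizontal saccades use the vertical component and vice versa.  Returns
    None when every sample is masked.
    """
    if axis == "horizontal":
        comp = np.asarray(vy, dtype=float)
    elif axis == "vertical":
        comp = np.asarray(vx, dtype=float)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    if valid is None:
        valid = np.ones(comp.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        return None
    return float(np.max(np.abs(comp[valid])))


def detect_saccade(
    trace: GazeTrace,
    meta,
    vx: np.ndarray,
    vy: np.ndarray,
    onset_threshold: float = 30.0,
    peak_mode: str = "component",
) -> SaccadeEvent:
    """Locate the mid-saccade point and saccade onset for one trial.

    The mid-saccade point is the first moment the along-axis gaze coordinate
    crosses the meridian (coordinate 0) moving toward the target, located by
    linear interpolation between samples and rounded to the 1-ms grid.  The
    onset is the last upward crossing of ``onset_threshold`` by the
    along-axis |velocity| before the mid-saccade point.  The crossing may
    precede the cue; the resulting negative latency is left to the exclusion
    rules.

    Parameters
    ----------
    meta:
        TrialMeta with ``direction``, ``cue_onset``, ``fixation_pos``,
        ``target_pos``; fixation and target must lie on opposite sides of
        the meridian.
    """
    axis = axis_of(meta.direction)
    if axis == "horizontal":
        coord, v_along = trace.x, np.asarray(vx, dtype=float)
        fix_c, targ_c = meta.fixation_pos[0], meta.target_pos[0]
    else:
        coord, v_along = trace.y, np.asarray(vy, dtype=float)
        fix_c, targ_c = meta.fixation_pos[1], meta.target_pos[1]
    if fix_c * targ_c >= 0:
        raise ValueError("fixation and target must straddle the meridian")
    s_t = np.sign(targ_c)

    ok = trace.valid
    c = coord
    # first pair straddling the meridian toward the target, both samples valid
    left = (s_t * c[:-1] < 0) & (s_t * c[1:] >= 0) & ok[:-1] & ok[1:]
    idx = np.nonzero(left)[0]
    if idx.size == 0:
        raise SaccadeError("no saccade: gaze never crossed the meridian")
    i = int(idx[0])
    denom = c[i + 1] - c[i]
    frac = 0.0 if denom == 0 else -c[i] / denom
    mid_t = float(np.round(trace.t[i] + frac * (trace.t[i + 1] - trace.t[i])))

    # onset: last rise of |v_along| through the threshold at or before mid
    i_mid = int(np.searchsorted(trace.t, mid_t))
    i_mid = min(i_mid, len(trace) - 1)
    above = np.abs(v_along[: i_mid + 1]) >= onset_threshold
    rises = np.nonzero(above[1:] & ~above[:-1])[0]
    if rises.size:
        onset = float(trace.t[int(rises[-1]) + 1])
    elif above.any():
        onset = float(trace.t[int(np.argmax(above))])
    else:
        onset = float(trace.t[0])

    pv = peak_velocity(vx, vy, trace.valid, mode=peak_mode)
    ov = orthogonal_velocity(vx, vy, axis, trace.valid)
    return SaccadeEvent(
        onset=onset,
        mid_saccade_t=mid_t,
        latency=onset - float(meta.cue_onset),
        peak_velocity=np.nan if pv is None else pv,
        peak_orthogonal_velocity=np.nan if ov is None else ov,
        axis=axis,
    )
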