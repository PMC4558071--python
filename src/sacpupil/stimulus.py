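"""Polarity-reversing grating stimulus: calibration, rendering, conditions.

The background stimulus is a full-contrast sinusoid grating that reverses
polarity on every display frame.  Above the flicker-fusion rate it looks like
a uniform gray field during fixation, but it contains two ambiguous motion
signals: the frame sequence is equally consistent with the grating drifting
half a cycle per frame in either direction perpendicular to its orientation.

Velocity matching: if the eyes travel exactly half a grating cycle between
two frames, the grating is momentarily stabilized on the retina and becomes
visible mid-saccade.  ``ideal_spatial_frequency`` inverts that rule to pick
the spatial frequency whose motion speed equals a given peak eye velocity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Tuple

import numpy as np

from .eye_signal import axis_of


@dataclass(frozen=True)
class GratingStimulus:
    """Parameters of the flickering sinusoid background.

    ``phase`` is in cycles; phase 0 puts a luminance maximum at the screen
    center on even frames.  Luminances are linearized (cd/m^2): gamma
    calibration of the display is taken as given, so polarity reversal is
    exact in luminance.
    """

    orientation: str                 # 'vertical' | 'horizontal' (bar orientation)
    spatial_frequency: float         # cycles/deg
    frame_rate: float = 150.0        # Hz
    L_min: float = 5.2               # cd/m^2
    L_max: float = 95.1              # cd/m^2
    size_deg: float = 22.6           # width = height
    phase: float = 0.0               # cycles

    def __post_init__(self) -> None:
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be > 0")
        if self.L_min >= self.L_max:
            raise ValueError("L_min must be < L_max")

    @property
    def motion_axis(self) -> str:
        """Axis of the ambiguous motion: perpendicular to the bars."""
        return "horizontal" if self.orientation == "vertical" else "vertical"

    @property
    def motion_speed(self) -> float:
        """Speed of either motion interpretation: half a cycle per frame (deg/s)."""
        return self.frame_rate / (2.0 * self.spatial_frequency)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class MotionInterpretation:
    """One of the two opposite readings of the flickering grating."""

    sign: int          # +1 or -1 along the motion axis
    speed: float       # deg/s, positive
    axis: str          # 'horizontal' | 'vertical'

    @property
    def velocity(self) -> float:
        return self.sign * self.speed


def ideal_spatial_frequency(peak_velocity: float, frame_rate: float) -> float:
    """Spatial frequency (cycles/deg) matched to a given peak eye velocity.

    Chosen so the eyes' maximum travel between two frames equals half a
    grating cycle: travel = v / f degrees per frame, and half a cycle is
    1 / (2 * SF) degrees, giving SF = f / (2 v).  Equivalently, the motion
    speed of the resulting grating equals ``peak_velocity``.
    """
    if peak_velocity <= 0 or frame_rate <= 0:
        raise ValueError("peak_velocity and frame_rate must be > 0")
    return frame_rate / (2.0 * peak_velocity)


def motion_interpretations(
    stim: GratingStimulus,
) -> Tuple[MotionInterpretation, MotionInterpretation]:
    """The two opposite, equal-speed motion readings of the grating."""
    speed = stim.motion_speed
    axis = stim.motion_axis
    return (
        MotionInterpretation(sign=+1, speed=speed, axis=axis),
        MotionInterpretation(sign=-1, speed=speed, axis=axis),
    )


def render_frame(
    stim: GratingStimulus, frame_index: int, n_pixels: int
) -> np.ndarray:
    """1-D luminance profile (cd/m^2) of one display frame.

    The profile is taken along the motion axis across the stimulus extent,
    centered on the screen center.  Consecutive frames are exact polarity
    reversals: frame i and frame i+1 sum pointwise to L_min + L_max, so their
    mean is spatially uniform — the fused appearance during fixation.
    Raises if fewer than 2 pixels per cycle would sample the sinusoid.
    """
    if n_pixels < 2:
        raise ValueError("need at least 2 pixels")
    pitch = stim.size_deg / n_pixels
    if 1.0 / (stim.spatial_frequency * pitch) < 2.0:
        raise ValueError(
            "undersampled grating: fewer than 2 pixels per cycle"
        )
    pos = (np.arange(n_pixels) - (n_pixels - 1) / 2.0) * pitch
    mid = 0.5 * (stim.L_min + stim.L_max)
    amp = 0.5 * (stim.L_max - stim.L_min)
    polarity = 1.0 if frame_index % 2 == 0 else -1.0
    carrier = np.cos(2.0 * np.pi * (stim.spatial_frequency * pos + stim.phase))
    return mid + polarity * amp * carrier


def condition_for(saccade_direction: str, orientation: str) -> str:
    """Condition label implied by saccade direction and grating orientation.

    A grating perpendicular to the saccade moves along the saccade axis, so
    the saccade can stabilize it: 'intrasaccadic_percept'.  A parallel
    grating moves orthogonally to the saccade and is never stabilized:
    'no_percept'.
    """
    saccade_axis = axis_of(saccade_direction)
    if orientation not in ("vertical", "horizontal"):
        raise ValueError(f"unknown orientation {orientation!r}")
    grating_axis = "horizontal" if orientation == "horizontal" else "vertical"
    perpendicular = saccade_axis != grating_axis
    return "intrasaccadic_percept" if perpendicular else "no_percept"


def orientation_for(saccade_direction: str, condition: str) -> str:
    """Grating orientation that realizes a condition for a saccade direction."""
    saccade_axis = axis_of(saccade_direction)
    if condition == "intrasaccadic_percept":
        return "vertical" if saccade_axis == "horizontal" else "horizontal"
    if condition == "no_percept":
        return "horizontal" if saccade_axis == "horizontal" else "vertical"
    raise ValueError(f"unknown condition {condition!r}")
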