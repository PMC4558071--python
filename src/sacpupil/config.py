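"""Run-level configuration shared by all pipeline stages.

Every threshold and convention of the analysis lives in :class:`RunConfig` so
that a run is fully described by one JSON document plus a seed.  Unknown keys
in a config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import IO, Tuple, Union


@dataclass(frozen=True)
class ScreenGeometry:
    """Mapping between screen pixels and degrees of visual angle.

    The analysis works in degrees from screen center with y positive upward;
    raw eye-tracker files are in screen pixels with y positive downward.  The
    mapping is linear (small-angle approximation, as is conventional for
    eye-tracker output at typical viewing distances).
    """

    width_px: int = 1024
    height_px: int = 768
    px_per_deg: float = 30.0

    def to_degrees(self, x_px: float, y_px: float) -> Tuple[float, float]:
        x = (x_px - self.width_px / 2.0) / self.px_per_deg
        y = (self.height_px / 2.0 - y_px) / self.px_per_deg
        return x, y

    def to_pixels(self, x_deg: float, y_deg: float) -> Tuple[float, float]:
        x = self.width_px / 2.0 + x_deg * self.px_per_deg
        y = self.height_px / 2.0 - y_deg * self.px_per_deg
        return x, y


@dataclass
class RunConfig:
    """All analysis parameters, with the study's defaults.

    Attributes
    ----------
    smoothing_window_ms:
        Width of the Hanning window applied to eye position (ms; odd).
    onset_threshold:
        Along-axis velocity threshold for saccade-onset detection (deg/s).
    peak_mode:
        'component' takes the maximum over time of max(|vx|, |vy|);
        'vector' uses the Euclidean speed.  The componentwise reading follows
        the operative description of peak velocity; the vector alternative is
        kept because the two phrasings of the procedure differ.
    blink_margin_ms / max_blink_ms:
        Margin added around blink gaps before cubic-spline reconstruction, and
        the longest gap that is reconstructed at all.
    normalization:
        'divisive' (pupil / baseline, so 1.0 = baseline) or 'subtractive'.
    baseline_window_ms / epoch_window_ms:
        Windows relative to the mid-saccade point (ms, inclusive bounds).
    part1_velocity_bounds:
        Plausibility band for peak velocity of 17 deg saccades (deg/s,
        inclusive); trials outside it do not count toward the per-direction
        median.
    part1_n_required:
        Number of valid trials the per-direction median is based on.
    max_latency_ms / max_peak_velocity / max_deviation_deg:
        Trial-exclusion thresholds: latency above this (or below 0) drops the
        trial; peak velocity above this is treated as data loss; gaze farther
        than this from the fixation dot (pre) or target (post) drops the trial.
    exclusion_halfwindow_ms:
        Half width of the window around the mid-saccade point that the gaze
        deviation checks ignore.
    frame_rate:
        Display frame rate (Hz) used by the grating calibration.
    theta_stabilization:
        Retinal-speed threshold (deg/s) under which the grating counts as
        stabilized; defines the predicted percept window.
    t_threshold / min_run_ms / two_sided:
        Reliability rule for the sample-wise sweep: |t| (or t, if one-sided)
        must exceed the threshold for at least ``min_run_ms`` consecutive
        samples.
    decimate:
        Grid-coarsening factor for the sweep (1 = full 1-ms grid).
    correct_position_artifacts:
        Regress gaze-angle artifacts out of pupil size before epoching.
        Off by default: eye position has both real and artifactual effects on
        measured pupil size, so a linear correction is not trustworthy.
    reml:
        Fit mixed models by restricted maximum likelihood.
    """

    smoothing_window_ms: int = 11
    onset_threshold: float = 30.0
    peak_mode: str = "component"
    blink_margin_ms: int = 50
    max_blink_ms: int = 500
    normalization: str = "divisive"
    baseline_window_ms: Tuple[int, int] = (-105, -95)
    epoch_window_ms: Tuple[int, int] = (-300, 1200)
    part1_velocity_bounds: Tuple[float, float] = (220.0, 664.0)
    part1_n_required: int = 40
    max_latency_ms: float = 2000.0
    max_peak_velocity: float = 1000.0
    max_deviation_deg: float = 3.3
    exclusion_halfwindow_ms: float = 100.0
    frame_rate: float = 150.0
    theta_stabilization: float = 50.0
    t_threshold: float = 2.0
    min_run_ms: float = 200.0
    two_sided: bool = True
    decimate: int = 1
    correct_position_artifacts: bool = False
    reml: bool = True
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        if self.peak_mode not in ("component", "vector"):
            raise ValueError(f"unknown peak_mode {self.peak_mode!r}")
        if self.normalization not in ("divisive", "subtractive"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.decimate < 1:
            raise ValueError("decimate must be >= 1")

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        return d

    def to_json(self, sink: Union[str, IO[str]]) -> None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "geometry" in d and isinstance(d["geometry"], dict):
            geo = d["geometry"]
            geo_known = {f.name for f in dataclasses.fields(ScreenGeometry)}
            bad = set(geo) - geo_known
            if bad:
                raise ValueError(f"unknown geometry keys: {sorted(bad)}")
            d["geometry"] = ScreenGeometry(**geo)
        for key in ("baseline_window_ms", "epoch_window_ms", "part1_velocity_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, source: Union[str, IO[str]]) -> "RunConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                d = json.load(fh)
        return cls.from_dict(d)
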