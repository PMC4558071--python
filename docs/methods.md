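# Methods

This note documents the models, conventions and numerical choices behind
`sacpupil`, in the spirit of a package methods appendix: what is computed,
under which assumptions, and where the design was genuinely open.

## Coordinate and signal conventions

All gaze data live on a gap-free 1-ms grid (1 kHz), in degrees of visual
angle from screen center with y positive upward; readers convert
pixel-based sources (the EyeLink-style `asc_like` dialect) through a linear
`ScreenGeometry`, flipping y.  This makes "up" saccades have positive
along-axis velocity, so prose and signs agree.  A missing sample is a
masked sample: the raw blink sentinel (pupil = 0) is converted to a mask on
ingestion and never treated as a measurement.

Eye position is smoothed with a unit-sum Hanning window (default 11 ms,
odd number of samples) with reflection padding, so constants pass through
unchanged and no lag is introduced.  Velocity is a central finite
difference (one-sided at the ends), in °/s.  The pupil channel is never
smoothed; its only repair is blink reconstruction.

## Saccade landmarks

Trials are time-locked to the **mid-saccade point**: the first moment the
along-axis gaze coordinate crosses the screen meridian (coordinate zero)
moving toward the target, found by linear interpolation between samples
and rounded to the 1-ms grid.  The crossing search covers the whole trial,
so anticipatory saccades produce a valid (negative-latency) event and are
removed by the exclusion rules rather than by the detector.

Saccade onset is the last upward crossing of the along-axis |velocity|
through a threshold (default 30 °/s, a standard velocity-criterion value;
the original acquisition used the vendor's online parser, whose criterion
is not part of the analysis) before the mid-saccade point; latency is
onset minus cue onset.

**Peak velocity** is the maximum over time of max(|vx|, |vy|) — the highest
single-axis speed at any moment in the trial.  The procedure is described
in two slightly different ways in the source analysis ("maximum of the
peaks of the horizontal or vertical velocity profiles" vs "highest speed
of the eyes at any moment and in any direction"); the componentwise
reading follows the operative sentence, and the Euclidean-norm alternative
is available via `peak_mode="vector"`.  For straight saccades the two
agree; for curved ones the vector norm is slightly larger.  An all-masked
trial yields an *undeterminable* peak (None), never a number.

## Pupil preprocessing

Blinks are runs of masked samples.  Each run is extended by a margin
(default 50 ms per side — the pupil signal is distorted just before and
after the lids close) and replaced by a cubic spline through four anchor
samples at run-edge ± margin and ± 2·margin, a standard reconstruction
scheme in pupillometry.  Runs longer than 500 ms, and runs whose anchors
fall off the trace or on other masked samples (blinks at the trace edge),
stay masked.  Samples outside extended runs are never altered.

Epochs cover −300 … +1200 ms around the mid-saccade point (1,501 samples).
The baseline is the mean reconstructed pupil *area* from −105 to −95 ms;
normalization is divisive by default (1.0 = baseline), making epochs
scale-invariant in the tracker's arbitrary units; a subtractive mode
exists for users who prefer differences in raw units.  Whether the
original analysis used the reconstructed or raw series for the baseline,
and ratio or difference normalization, is not documented; the defaults
here (reconstructed, divisive) were chosen because a baseline must not be
blink-contaminated and a ratio is unit-free.  An epoch whose baseline
window has no valid sample is rejected with a reason.

Gaze-angle ("position") artifacts — video trackers misestimate pupil area
as a function of where the eye points — can be regressed out per
participant (`remove_position_artifact`, a linear fit of baseline area on
fixation x/y), but the correction is **off by default**: eye position has
both a real and an artifactual effect on measured pupil size, with
opposite signs in this paradigm, so a linear correction is not
trustworthy.  The synthetic generator plants such artifacts so the
machinery stays exercised.

## Trial exclusion

Rules are checked in a fixed order and only the first firing rule is
recorded, so per-reason counts are unambiguous; the keep/drop decision is
order-independent.  Thresholds: latency < 0 ms (anticipation) or
> 2000 ms; peak velocity undeterminable or > 1000 °/s (data loss); gaze
more than 3.3° (Euclidean) from the fixation dot before the saccade or
from the target after it.  The deviation checks ignore a 200-ms window
around the mid-saccade point, read here as centered (±100 ms) — the most
common convention; whether it was centered or one-sided is not stated in
the source.  The calibration part's plausibility band (220–664 °/s for
17° saccades) reads "above"/"below" strictly, so the bounds themselves are
valid; the original session *re-ran* out-of-band trials, which is
acquisition behaviour — the pipeline only flags them.

## Grating calibration and the retinal model

`ideal_spatial_frequency(v, f) = f / (2 v)` makes the eyes' travel between
frames equal half a grating cycle; equivalently the grating's two motion
interpretations (±`f / (2 · SF)` along the axis perpendicular to its bars)
move exactly at the calibrated peak velocity.  Rendering works on a
linearized luminance axis (the display is assumed gamma-calibrated), so
frame *i* and *i+1* sum pointwise to `L_min + L_max` and fuse to a uniform
field at fixation.  Phase 0 puts a luminance maximum at screen center.

The stabilization index is `s(t) = min(|+speed − v(t)|, |−speed − v(t)|)`,
where `v(t)` is the eye-velocity component along the grating's motion
axis: the along-saccade component for a perpendicular grating (percept
geometry), the orthogonal component for a parallel one (no-percept
geometry, where only saccade curvature can partially stabilize the
grating).  The predicted percept window is the maximal run with
`s(t) < θ`; θ defaults to 50 °/s.  No quantitative visibility threshold
exists for this paradigm, so θ is an explicit, reported config value and
window durations should be compared across conditions, not read as
absolute visibility predictions.  Peak-velocity error is
|actual − optimal|; the signed miss is available where the direction
matters.  Note an asymmetry that matters for analyses: an overshooting
saccade still passes *through* the grating speed (s reaches ~0), whereas an
undershooting one leaves a residual retinal speed equal to the shortfall.

## The sample-wise mixed-model sweep

At every sample of the (possibly decimated) epoch grid, normalized pupil
size is fit by a linear mixed-effects model with by-participant random
intercept and random slopes for all predictors.  Model formulas:
`condition` (treatment-coded, reference no-percept),
`condition*direction` (direction as a two-level axis factor, reference
horizontal — the experimental contrast is horizontal vs vertical), and
`condition+direction`, which adds direction as a *nuisance* factor for
subset analyses: saccades toward different screen positions carry
different gaze-angle artifacts, and pooling e.g. up and down saccades
without that term converts random condition-cell imbalance into sustained
noise.

Estimation choices the source leaves open, fixed here as: REML;
random-effects covariance diagonal (intercept and slopes uncorrelated —
more robust with ~10 participants than a full covariance); L-BFGS
warm-started from the neighbouring sample, with a cold restart if the warm
start lands on a degenerate boundary; on failure the sample is refit with
random slopes dropped and *flagged*, and flagged samples can never enter a
reliable interval.  t = estimate / SE; no p-values are computed in the
sweep.

**Reliability rule:** an effect is reliable over maximal runs where
|t| > 2 (two-sided by default — the effect of interest is a *decrease*,
so one-sided `t > 2` would never fire; a one-sided mode exists) lasting at
least 200 ms, with the run length converted to samples via the grid step
(20 samples on a 10-ms grid).  Intervals are half-open `[start, end)` in
ms.

Post-hoc utilities follow the original logic: strict-below median splits
of per-trial metrics within participant × direction groups; per-participant
SD (ddof = 1) of peak velocity and mean peak orthogonal velocity as
dispersion measures; classical two-sided paired t-tests (df = n − 1) on
those, which do report p-values.

## The synthetic-data generator

The generator emulates the two-part session the analysis assumes.
Kinematics: along-axis velocity is a raised-cosine pulse whose duration
`D = 2A / V_p` makes the displacement integral equal the amplitude
(default 17°, dots at ±8.5°) and the maximum equal the drawn peak
velocity; curvature is a zero-integral biphasic pulse, so the eye returns
to the saccade axis by landing.  Positions are analytic integrals, not
numeric cumsums.  Defaults: mean peak 400 °/s; per-trial SD 80 °/s
(horizontal) vs 130 °/s (vertical) and curvature 40 ± 20 vs 110 ± 30 °/s,
reproducing the two robust direction differences (vertical saccades are
more variable and more curved, with orthogonal peaks approaching
150 °/s); per-participant direction means jittered with SD 40 °/s;
latency 150 ± 30 ms.

Pupil: baseline (≈1200 a.u. between participants, SD 150) times
1 + dilation − constriction − condition term, each component an impulse
convolved with an Erlang-family kernel `(t/t_max)^n · exp(n(1 − t/t_max))`
(n = 3).  Dilation (0.04 ratio units, t_max 350 ms) is cue-locked (motor
preparation); the saccade-generic constriction (0.12, t_max 600 ms) starts
220 ms after the mid-saccade point; the percept-driven extra constriction
(default 0.04) starts 300 ms after it.  White measurement noise SD 10 a.u.
(~0.8% of baseline), per-trial amplitude jitter CV 0.15, per-participant
effect scaling SD 0.3, blink probability 0.1/trial (≈120 ms), gaze noise
0.02°, and gaze-angle artifact slopes of 2 (x) and 3 (y) a.u./° — a few
percent of baseline across the ±8.5° display, in line with reported
video-tracker artifacts.

Percept strength is kinematic rather than a pure condition label: the
extra-constriction amplitude is scaled by a Gaussian falloff
`exp(−(Δv / 150 °/s)²)`, where Δv is the peak-velocity error in the
percept condition and the gap between orthogonal peak velocity and grating
speed in the no-percept condition (partial stabilization by curvature).
This is what makes the direction post-hocs meaningful in simulation:
inflating vertical variability and curvature dilutes the vertical
condition contrast, and the two median splits recover it.  The true
effect size in ratio units is not printed numerically anywhere in the
source (it is a figure-scale quantity), so 0.04 is a generator choice of
the right visual magnitude, not a literature value.

What the generator does *not* emulate: oculomotor plant dynamics beyond
the raised-cosine profile, pupil foreshortening geometry, slow arousal
drifts, or temporally correlated measurement noise.  Passing end-to-end
tests therefore show that the pipeline recovers what it assumes, under
realistic amplitudes and noise — not that real data are this well-behaved.

## Problem sizes and determinism

Study-scale defaults (50 trials per direction × condition cell) mirror the
original data volume.  The bundled end-to-end studies run desk-scale
versions: 10 participants with 4 trials/cell (recovery and null
false-positive studies, 20 seeded replicates each) or 12 trials/cell (the
direction post-hoc study, 3 seeds), all on a 10-ms decimated grid, where
the 200-ms reliability rule becomes 20 consecutive samples.  These sizes
were chosen so the studies run on a single desktop CPU in minutes while
keeping per-replicate power high.  Every random draw flows from one
integer seed (`numpy.random.default_rng`); replicate seeds are derived
arithmetically from it, and identical seeds give byte-identical datasets
and outputs.

## Known limitations

- The sweep supports the three model formulas above, not arbitrary
  formula strings.
- Mid-saccade detection assumes one goal-directed saccade per trial;
  corrective secondary saccades are not modelled separately (they surface
  as post-saccadic deviation exclusions when large).
- Blink reconstruction needs two clean anchor stretches on both sides; a
  blink overlapping the epoch edge stays masked and may cost the epoch its
  baseline.
- The retinal model is purely geometric: it predicts stabilization, not
  visibility (no contrast sensitivity, temporal filtering, or masking by
  pre/post-saccadic stimulation).
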