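"""Blink repair and baseline-normalized epoching of a pupil trace.

A blink is a run of missing samples.  It is repaired by a cubic spline
through anchor points around the (margin-extended) gap, after which the
trace is cut into a mid-saccade-locked epoch and divided by its baseline
(mean area from 105 to 95 ms before the mid-saccade point).
"""

import numpy as np

import sacpupil as sp
from sacpupil.eye_signal import GazeTrace

rng = np.random.default_rng(4)
n = 4000
t = np.arange(n)
pupil = 1200.0 - 60.0 * sp.synth.pupil_kernel(t - 2200.0, 600.0) \
    + rng.normal(0, 5, n)

valid = np.ones(n, bool)
valid[1500:1620] = False           # a 120-ms blink
pupil_masked = np.where(valid, pupil, np.nan)
trace = GazeTrace(t=t, x=np.zeros(n), y=np.zeros(n), pupil=pupil_masked,
                  valid=valid)

repaired = sp.reconstruct_blinks(trace, margin_ms=50)
err = np.nanmax(np.abs(repaired.pupil[1500:1620] - pupil[1500:1620]))
print(f"blink samples repaired : {int((~valid).sum())}")
print(f"max reconstruction err : {err:.1f} a.u. "
      f"({100 * err / 1200:.2f}% of baseline)")

epoch = sp.epoch_and_normalize(repaired, mid_saccade_t=2000)
window = (epoch.rel_t >= -105) & (epoch.rel_t <= -95)
print(f"baseline               : {epoch.baseline:.1f} a.u.")
print(f"baseline-window mean   : {np.nanmean(epoch.values[window]):.9f} "
      f"(1.0 = at baseline)")
print(f"minimum of epoch       : {np.nanmin(epoch.values):.3f} at "
      f"{epoch.rel_t[np.nanargmin(epoch.values)]} ms after mid-saccade")
# Values below 1.0 are constriction relative to the pre-saccadic baseline.
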