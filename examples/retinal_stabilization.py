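"""Why only the perpendicular grating becomes visible mid-saccade.

Computes retinal-speed profiles of a velocity-matched grating for the two
geometries: perpendicular to the saccade (percept condition — the along-axis
eye velocity cancels one motion interpretation) and parallel to it
(no-percept condition — only saccade curvature works against the motion).
"""

import numpy as np

import sacpupil as sp
from sacpupil.stimulus import GratingStimulus

peak = 400.0
sf = sp.ideal_spatial_frequency(peak, 150.0)

seg = sp.simulate_saccade(17.0, "right", peak, curvature=120.0)
vx = np.gradient(seg.x, 0.001)
vy = np.gradient(seg.y, 0.001)

for label, orientation in [("percept (perpendicular)", "vertical"),
                           ("no-percept (parallel)", "horizontal")]:
    stim = GratingStimulus(orientation, sf)
    prof = sp.stabilization_profile(seg.t, vx, vy, stim, theta=50.0)
    window = ("none" if prof.percept_window is None
              else f"{prof.percept_window[0]:.0f}-{prof.percept_window[1]:.0f} ms"
                   f" ({prof.window_duration:.0f} ms)")
    print(f"{label:28s} min retinal speed {prof.s.min():7.1f} deg/s, "
          f"window {window}")

err = sp.peak_velocity_error(actual=340.0, optimal=peak)
print(f"\na saccade peaking at 340 deg/s misses the optimum by {err:.0f} deg/s"
      " -> weaker stabilization, weaker percept")
# Near-zero minimum retinal speed = the grating almost freezes on the
# retina; the percept window is the predicted moment of visibility.
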