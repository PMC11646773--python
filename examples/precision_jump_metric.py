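"""Score a precision-jump trial end to end.

Simulates a jump landing 35 mm past the target line, conditions the signals
the way real recordings are conditioned, detects the landing from the
vertical-force step, and reads off the landing error from the toe marker.
"""

import posturekit as pk
from posturekit.signals import condition_markers, condition_plate

geometry = pk.TaskGeometry()
trial = pk.simulate_jump_trial(geometry, offset=35.0, landing_time=1.2, seed=7)

cfg = pk.FilterConfig()
plate = condition_plate(trial.plates[0], cfg)
markers = condition_markers(trial.markers, trial.marker_rate, cfg)

t_land = pk.detect_landing(plate, threshold=20.0, hold_ms=20.0)
err = pk.precision_jump_error(markers["toe"], trial.marker_rate, geometry, t_land)

print(f"detected landing at {t_land:.3f} s (programmed 1.200 s)")
print(f"precision-jump target error: {err.value:.2f} mm (programmed 35 mm)")
# The landing is the first sustained vertical-force contact; the error is
# the horizontal distance of the big-toe marker from the target line at
# that instant - lower is better.
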