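"""Event-level simulation: list-mode events to COD traces, TOF vs non-TOF.

Draws annihilation events from a brain-like phantom that translates by
+3 mm in x halfway through a 10-min acquisition, bins them to 1-s COD
traces, and compares how well TOF-bin centers versus LOR midpoints recover
the step.  TOF localization recovers the full 3 mm; chord midpoints dilute
each event's position toward the bore axis, shrinking (but not erasing)
the step.
"""

import numpy as np

from codmotion import (MotionSchedule, brain_like_phantom, compute_cod,
                       simulate_events)

phantom = brain_like_phantom(rate0=5_000.0)
motion = MotionSchedule.from_translations([300.0], [[3.0, 0.0, 0.0]])

for mode in ("tof", "nontof"):
    events = simulate_events(phantom, motion, duration=600.0, seed=7, mode=mode)
    trace = compute_cod(events, bin_duration=1.0)
    before = np.nanmean(trace.cx[:300])
    after = np.nanmean(trace.cx[300:])
    sd = np.nanstd(trace.cx[:300])
    print(f"{mode:6s}: COD x step = {after - before:+.2f} mm "
          f"(true +3.00), per-bin noise SD = {sd:.2f} mm, "
          f"{len(events)} events")
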