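"""Motion-free-frame pruning: discard frames with residual intra-frame motion.

A 20-min trace contains one clean 6-mm step plus a burst of fast oscillatory
motion (2-mm, 4-s period) that no step model can represent — detection even
warns that its target error is unreachable, the signature of over-frequent
motion.  The 2xSD gate then discards frames with residual intra-frame
variation, and a low-count threshold removes frames too sparse to register.
The summary line mirrors how gating results are reported for real scans:
seconds discarded and percent of the scan.
"""

import numpy as np

from codmotion import (DetectionConfig, detect_3d, discarded_summary,
                       prune_intra_motion, prune_low_count)
from codmotion.trace import CODTrace

rng = np.random.default_rng(3)
n = 1200
v = np.concatenate([rng.normal(0, 0.4, 600), rng.normal(6, 0.4, 600)])
v[320:440] += 2.0 * np.sin(np.arange(120) * np.pi / 2)   # untrackable burst
trace = CODTrace(1.0, v, rng.normal(0, 0.4, n), rng.normal(0, 0.4, n),
                 np.full(n, 1000))

result = detect_3d(trace, DetectionConfig(alpha=1.0, n_max=20,
                                          partition_duration=300.0))
decisions = prune_intra_motion(result, trace)
decisions = prune_low_count(decisions, trace, min_counts=5_000)

kept = [d for d in decisions if d.status == "kept"]
print(f"{len(decisions)} detected frames, {len(kept)} kept; discarded:")
for d in decisions:
    if d.status == "kept":
        continue
    sd = "  -  " if np.isnan(d.sd["x"]) else f"{d.sd['x']:.2f}"
    print(f"  [{d.start:5.0f}, {d.end:5.0f}) s  SDx={sd} mm  "
          f"2x pred={2 * d.predicted_sd['x']:.2f} mm  counts={d.counts:6d}  "
          f"{d.status}")

s = discarded_summary(decisions)
print(f"\ndiscarded {s['discarded_seconds']:.0f} s "
      f"({s['discarded_percent']:.1f}%) of the {s['total_seconds']:.0f}-s scan")
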