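"""Simulate a tracked fly and repair its misdetections.

One synthetic fly is recorded for an hour at 5 fps with a 1% misdetection
rate (the tracker occasionally reports a low-confidence position outside
the chamber).  Cleaning flags those frames and replaces each with the
midpoint of the flanking in-chamber detections; the numbers below show
that the repair is accurate to within a few pixels of the hidden truth.
"""

import numpy as np

from flybeam import SimulationConfig, clean_series, simulate_fly

cfg = SimulationConfig(duration_s=3600.0, misdetect_rate=0.01, seed=42)
series, truth = simulate_fly(cfg)

cleaned, report = clean_series(series, geometry=cfg.chamber)
print(f"{report['n_frames']} frames, {report['n_flagged']} flagged and interpolated")

mis = truth.misdetect_mask
err = np.hypot(cleaned.x[mis] - truth.true_x[mis], cleaned.y[mis] - truth.true_y[mis])
print(f"injected misdetections: {mis.sum()} ({100 * mis.mean():.2f}% of frames)")
print(f"mean repair error at those frames: {err.mean():.2f} px "
      f"(step scale {cfg.step_scale} px)")

inside = all(cfg.chamber.contains(x, y) for x, y in zip(cleaned.x, cleaned.y))
print(f"all cleaned positions inside the chamber: {inside}")
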