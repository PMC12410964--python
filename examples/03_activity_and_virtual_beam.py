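"""Circadian activity of a night-shifted cohort, by distance and virtual beam.

Sixteen flies are simulated over three 12:12 LD days with their rest-to-
move rate doubled at night and 3x startle bursts after every light switch.
The pipeline bins distance in 10-minute windows, counts virtual beam
crossings at the chamber midline, extracts sleep bouts (>= 5 min without
a crossing), and recovers the generating night/day ratio.
"""

import numpy as np

from flybeam import (
    bin_activity,
    bin_crossings,
    clean_series,
    compare_totals,
    day_night_totals,
    frame_distances,
    simulate_experiment,
    sleep_bouts,
    virtual_dam,
)
from flybeam.scenarios import nocturnal_shift_scenario

cfg = nocturnal_shift_scenario(seed=1, n_days=3)
groups, _ = simulate_experiment(cfg, 16, master_seed=1)

day_tot, night_tot, crossings, sleep_min = [], [], [], []
for series, _ in groups["group"]:
    cleaned, _ = clean_series(series, geometry=cfg.chamber)
    b = bin_activity(frame_distances(cleaned), cleaned.frames, cfg.fps, 10,
                     duration_s=cleaned.duration_s)
    tot = day_night_totals(b, cfg.schedule)
    day_tot.append(tot["day"])
    night_tot.append(tot["night"])
    ev = virtual_dam(cleaned)
    crossings.append(len(ev))
    sleep_min.append(sum(bout.duration_s for bout in sleep_bouts(ev)) / 60.0)

ratio = np.sum(night_tot) / np.sum(day_tot)
t, p = compare_totals(np.array(day_tot), np.array(night_tot))
print(f"n = 16 flies, 3 LD days; generating night/day rate ratio = 2.0")
print(f"recovered night/day distance ratio: {ratio:.3f}")
print(f"Welch t-test, day vs night totals: t = {t:.2f}, p = {p:.2e}")
print(f"median beam crossings per fly:     {np.median(crossings):.0f}")
print(f"median sleep per fly:              {np.median(sleep_min):.0f} min over 3 days")
# The ratio near 2 shows the distance metric tracks the generating rates;
# the tiny p-value mirrors a strong day/night activity difference.
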