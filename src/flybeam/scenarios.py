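"""Canonical simulation scenarios used for validation and examples.

Each function builds the :class:`~flybeam.SimulationConfig` for one study
condition, so the same ground-truth parameterisation backs the examples,
the validation suite and the reproduction script:

* a **nocturnal shift** cohort (night entry rate twice the day rate, with
  startle bursts at the light transitions) — the pipeline should recover
  the 2:1 night/day distance ratio and place the startle peaks at the
  transitions;
* an **arrhythmic free-run** cohort (constant rate in constant darkness)
  — the average-day profile should be flat;
* a **food-preference** pair (yeast-biased vs unbiased cohorts in the
  two-food chamber) — the food-adjacent-bin occupancy should separate the
  groups.
"""

from __future__ import annotations

from .schedule import LightSchedule
from .simulate import SimulationConfig, preference_chamber

N_LOCOMOTION_FLIES = 16   # cohort size for locomotion comparisons
N_PREFERENCE_FLIES = 12   # cohort size for the two-food assay


def nocturnal_shift_scenario(seed: int, n_days: int = 3) -> SimulationConfig:
    """Night-active fly under 12:12 LD: night entry rate = 2 x day rate,
    3x startle bursts for 10 min after every light switch, no siesta."""
    return SimulationConfig(
        duration_s=n_days * 86400.0,
        schedule=LightSchedule.ld(n_days),
        day_rate=0.005,
        night_rate=0.010,
        startle_boost=3.0,
        startle_duration_s=600.0,
        siesta_depth=1.0,
        seed=seed,
    )


def arrhythmic_dd_scenario(seed: int, n_days: int = 3) -> SimulationConfig:
    """Clock-less control: constant entry rate in constant darkness."""
    return SimulationConfig(
        duration_s=n_days * 86400.0,
        schedule=LightSchedule.dd(n_days),
        day_rate=0.0075,
        night_rate=0.0075,
        startle_boost=1.0,
        siesta_depth=1.0,
        seed=seed,
    )


def preference_scenario(seed: int, duration_s: float = 1800.0) -> SimulationConfig:
    """Two-food chamber template; group overrides set ``food_bias``
    (0.6 for a yeast-preferring cohort, 0.0 for an indifferent one)."""
    return SimulationConfig(
        duration_s=duration_s,
        chamber=preference_chamber(),
        schedule=LightSchedule.ld(1),
        day_rate=0.02,
        night_rate=0.02,
        siesta_depth=1.0,
        food_label="yeast",
        seed=seed,
    )
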