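"""Ground-truthed synthetic fly trajectories.

The generator stands in for the camera, arena and tracking network: it
emits tracking tables in the same dialect the reader consumes, together
with the ground truth (true positions, behavioural state, injected
misdetections) that makes every downstream stage testable.

The behavioural model is a two-state (rest/move) Markov walker in a
reflecting rectangular chamber:

* in **rest** the position is fixed; the fly enters a move bout with a
  circadian-modulated per-frame probability
  ``r(t) = base_rate(phase) * startle(t) * siesta(t)``;
* in **move** it takes steps of half-normal length with a slowly turning
  heading, optionally biased toward a food wall, and returns to rest with
  probability ``move_exit_rate`` per frame.

This reproduces the qualitative features of real recordings — higher
activity in one phase, startle bursts after light transitions, a midday
siesta, food-proximity preference — with no claim of biological realism.
Misdetections are injected by replacing the reported position with a
point in a 20 px band outside the chamber at likelihood below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import ChamberGeometry, FoodRegion
from .schedule import LightSchedule
from .tracking_io import TrackingSeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "locomotion_chamber",
    "preference_chamber",
    "simulate_fly",
    "simulate_experiment",
]

MISDETECT_BAND_PX = 20.0


def locomotion_chamber(mm_per_px: float = 0.1) -> ChamberGeometry:
    """Default 23 x 15 mm locomotion chamber, long axis vertical, food at the bottom."""
    w, h = 15.0 / mm_per_px, 23.0 / mm_per_px
    return ChamberGeometry(
        x_min=0.0, y_min=0.0, x_max=w, y_max=h,
        food_regions=(FoodRegion("food", h - 5.0 / mm_per_px, h),),
        mm_per_px=mm_per_px,
    )


def preference_chamber(mm_per_px: float = 0.1) -> ChamberGeometry:
    """Default 50 x 10 mm two-food chamber: sugar at the top, yeast at the bottom."""
    w, h = 10.0 / mm_per_px, 50.0 / mm_per_px
    food_mm = 5.0 / mm_per_px
    return ChamberGeometry(
        x_min=0.0, y_min=0.0, x_max=w, y_max=h,
        food_regions=(
            FoodRegion("sugar", 0.0, food_mm),
            FoodRegion("yeast", h - food_mm, h),
        ),
        mm_per_px=mm_per_px,
    )


@dataclass
class SimulationConfig:
    """Full ground-truth parameterisation of one synthetic fly.

    Rates are per-frame probabilities at ``fps`` frames per second.  The
    defaults model a virgin female under 12:12 LD: more active by day,
    startle bursts after light switches, a midday siesta, no food bias.
    """

    duration_s: float = 3 * 86400.0
    fps: float = 5.0
    chamber: ChamberGeometry = field(default_factory=locomotion_chamber)
    schedule: LightSchedule | None = None   # defaults to 12:12 LD covering duration
    day_rate: float = 0.01                  # rest -> move entry probability, day phases
    night_rate: float = 0.005               # rest -> move entry probability, night phases
    move_exit_rate: float = 0.3             # move -> rest probability per frame
    startle_boost: float = 3.0              # entry-rate multiplier after an L<->D switch
    startle_duration_s: float = 600.0
    siesta_depth: float = 0.5               # entry-rate multiplier during the siesta window
    siesta_window_zt: tuple[float, float] = (5.0, 9.0)
    food_bias: float = 0.0                  # P(redraw heading toward the food) per move step
    food_label: str | None = None           # which food region attracts; default: the first
    step_scale: float = 5.0                 # px, half-normal step-length scale
    turn_sd: float = 0.5                    # radians
    misdetect_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("day_rate", "night_rate", "move_exit_rate", "food_bias", "misdetect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        if self.duration_s < 1.0:
            raise ValueError("duration must be at least one second")
        if self.schedule is None:
            n_days = max(1, int(np.ceil(self.duration_s / 86400.0)))
            self.schedule = LightSchedule.ld(n_days)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """What actually happened, frame by frame."""

    true_x: np.ndarray
    true_y: np.ndarray
    state: np.ndarray            # 0 = rest, 1 = move
    misdetect_mask: np.ndarray   # True where the reported position was corrupted
    entry_rate: np.ndarray       # the modulated rest->move rate r(t) per frame
    config: SimulationConfig


def _entry_rates(config: SimulationConfig) -> np.ndarray:
    """Per-frame rest->move entry probability r(t), fully modulated."""
    sched = config.schedule
    t = np.arange(config.n_frames) / config.fps
    t = np.clip(t, sched.start_s, np.nextafter(sched.end_s, -np.inf))
    day = sched.is_day(t)
    r = np.where(day, config.day_rate, config.night_rate).astype(float)
    for tr in sched.light_transitions():
        r = np.where((t >= tr) & (t < tr + config.startle_duration_s),
                     r * config.startle_boost, r)
    zt = ((t - sched.zt0) / 3600.0) % 24.0
    z0, z1 = config.siesta_window_zt
    in_siesta = (zt >= z0) & (zt < z1) & day
    r = np.where(in_siesta, r * config.siesta_depth, r)
    return np.clip(r, 0.0, 1.0)


def simulate_fly(config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 fly_id: str = "fly", chamber_id: str = "c00",
                 ) -> tuple[TrackingSeries, GroundTruth]:
    """Simulate one fly and return (reported tracking series, ground truth).

    The same ``config.seed`` always yields a bit-identical series.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geom = config.chamber
    n = config.n_frames
    rates = _entry_rates(config)

    u_entry = rng.random(n)
    u_exit = rng.random(n)
    steps = np.abs(rng.normal(0.0, config.step_scale, n))
    turns = rng.normal(0.0, config.turn_sd, n)
    u_food = rng.random(n)

    # headings toward the (first) food region's centre point on its wall
    if geom.food_regions and config.food_bias > 0.0:
        if config.food_label is None:
            food = geom.food_regions[0]
        else:
            matches = [r for r in geom.food_regions if r.label == config.food_label]
            if not matches:
                raise ValueError(f"no food region labelled {config.food_label!r}")
            food = matches[0]
        lo, hi = geom.long_interval
        # the food sits against the nearer wall of the long axis
        target_long = lo if abs(food.center - lo) < abs(food.center - hi) else hi
        if geom.long_axis == "vertical":
            tx = np.full(n, 0.5 * (geom.x_min + geom.x_max))
            ty = np.full(n, target_long)
        else:
            tx = np.full(n, target_long)
            ty = np.full(n, 0.5 * (geom.y_min + geom.y_max))
    else:
        tx = np.zeros(n)
        ty = np.zeros(n)

    x0 = rng.uniform(geom.x_min, geom.x_max)
    y0 = rng.uniform(geom.y_min, geom.y_max)
    heading0 = rng.uniform(-np.pi, np.pi)

    # heading noise applied when a step is redrawn toward the food target
    jitter = rng.normal(0.0, config.turn_sd, n)

    xs, ys, states = _walk_kernel(
        x0, y0, heading0, rates, config.move_exit_rate,
        u_entry, u_exit, steps, turns, u_food, jitter,
        tx, ty, config.food_bias,
        geom.x_min, geom.x_max, geom.y_min, geom.y_max,
    )

    # inject misdetections into the *reported* series
    mis = rng.random(n) < config.misdetect_rate
    rx = xs.copy()
    ry = ys.copy()
    lik = rng.uniform(0.95, 1.0, n)
    n_mis = int(mis.sum())
    if n_mis:
        side = rng.integers(0, 4, n_mis)
        off = rng.uniform(0.0, MISDETECT_BAND_PX, n_mis)
        along_x = rng.uniform(geom.x_min - MISDETECT_BAND_PX, geom.x_max + MISDETECT_BAND_PX, n_mis)
        along_y = rng.uniform(geom.y_min - MISDETECT_BAND_PX, geom.y_max + MISDETECT_BAND_PX, n_mis)
        mx = np.where(side == 0, geom.x_min - off,
             np.where(side == 1, geom.x_max + off, along_x))
        my = np.where(side == 0, along_y,
             np.where(side == 1, along_y,
             np.where(side == 2, geom.y_min - off, geom.y_max + off)))
        rx[mis] = mx
        ry[mis] = my
        lik[mis] = rng.uniform(0.0, 0.5, n_mis)

    series = TrackingSeries(
        frames=np.arange(n, dtype=np.int64), x=rx, y=ry, likelihood=lik,
        fps=config.fps, fly_id=fly_id, chamber_id=chamber_id,
    )
    truth = GroundTruth(true_x=xs, true_y=ys, state=states,
                        misdetect_mask=mis, entry_rate=rates, config=config)
    return series, truth


@njit(cache=False)
def _walk_kernel(x0, y0, heading0, rates, move_exit_rate,
                       u_entry, u_exit, steps, turns, u_food, jitter,
                       tx, ty, food_bias,
                       x_min, x_max, y_min, y_max):  # pragma: no cover
    n = rates.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    states = np.zeros(n, dtype=np.int8)
    x, y, heading = x0, y0, heading0
    state = 0
    for i in range(n):
        if state == 0:
            if u_entry[i] < rates[i]:
                state = 1
        else:
            if u_exit[i] < move_exit_rate:
                state = 0
        if state == 1:
            heading += turns[i]
            if food_bias > 0.0 and u_food[i] < food_bias:
                heading = np.arctan2(ty[i] - y, tx[i] - x) + jitter[i]
            x += steps[i] * np.cos(heading)
            y += steps[i] * np.sin(heading)
            for _ in range(64):
                moved = False
                if x < x_min:
                    x = 2.0 * x_min - x
                    moved = True
                elif x >= x_max:
                    x = 2.0 * x_max - x
                    moved = True
                if y < y_min:
                    y = 2.0 * y_min - y
                    moved = True
                elif y >= y_max:
                    y = 2.0 * y_max - y
                    moved = True
                if not moved:
                    break
        xs[i] = x
        ys[i] = y
        states[i] = state
    return xs, ys, states


def fly_seed(master_seed: int, group_index: int, fly_index: int) -> np.random.Generator:
    """Deterministic, stable per-fly generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, group_index, fly_index)))


def simulate_experiment(
    config_template: SimulationConfig,
    n_flies: int,
    phenotype_overrides: dict[str, dict] | None = None,
    master_seed: int | None = None,
):
    """Simulate one or more cohorts of flies.

    ``phenotype_overrides`` maps group labels to parameter overrides (e.g.
    ``{"virgin": {}, "mated": {"food_bias": 0.6}}``); with ``None`` a
    single group ``"group"`` is produced.  Per-fly seeds derive
    deterministically from ``master_seed`` (default: the template's seed).

    Returns ``(groups, summary)`` where ``groups`` maps label ->
    list of (series, truth) and ``summary`` is a tidy per-fly table of
    ground-truth day/night distance and food-end occupancy.
    """
    import pandas as pd

    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if phenotype_overrides is None:
        phenotype_overrides = {"group": {}}
    if master_seed is None:
        master_seed = config_template.seed

    groups: dict[str, list] = {}
    rows = []
    for g_idx, (label, overrides) in enumerate(phenotype_overrides.items()):
        cfg = replace(config_template, **overrides)
        flies = []
        for f_idx in range(n_flies):
            rng = fly_seed(master_seed, g_idx, f_idx)
            series, truth = simulate_fly(cfg, rng=rng,
                                         fly_id=f"{label}_{f_idx:02d}",
                                         chamber_id=f"{label[:1]}{f_idx:02d}")
            flies.append((series, truth))
            rows.append(_truth_summary(label, series.fly_id, truth))
        groups[label] = flies
    return groups, pd.DataFrame(rows)


def _truth_summary(group: str, fly_id: str, truth: GroundTruth) -> dict:
    cfg = truth.config
    d = np.hypot(np.diff(truth.true_x), np.diff(truth.true_y))
    t = np.arange(cfg.n_frames - 1) / cfg.fps
    sched = cfg.schedule
    t = np.clip(t, sched.start_s, np.nextafter(sched.end_s, -np.inf))
    day = sched.is_day(t)
    geom = cfg.chamber
    lo, hi = geom.long_interval
    coord = np.asarray(geom.long_coord(truth.true_x, truth.true_y))
    near_high_end = coord >= hi - 0.1 * (hi - lo)
    return {
        "group": group,
        "fly_id": fly_id,
        "true_day_distance_px": float(d[day].sum()),
        "true_night_distance_px": float(d[~day].sum()),
        "true_frac_moving": float(truth.state.mean()),
        "true_frac_near_high_end": float(near_high_end.mean()),
        "n_misdetections": int(truth.misdetect_mask.sum()),
    }
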