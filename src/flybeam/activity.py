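"""Locomotor-activity metrics and group statistics.

Three activity read-outs are computed from a cleaned trajectory:

* **binned distance** — frame-to-frame Euclidean distances summed per time
  bin (1/10/30/60 min), the direct video-based activity measure;
* **virtual beam crossings** — how often the fly crosses a virtual
  infrared beam at the chamber midline, emulating the classic
  beam-interruption activity monitors so both methods can be compared on
  the same recordings;
* **sleep bouts** — maximal intervals of at least five minutes without a
  beam crossing, the operational sleep definition inherited from the
  beam-monitor literature.

Group-level summaries (mean/median traces, average day, day/night totals)
and the statistical comparisons between groups (Welch t-tests, hourly
Mann-Whitney tests with FDR control) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cleaning import CleanedSeries
from .errors import (
    GridAlignmentError,
    InsufficientDaysError,
    StatisticUndefinedError,
)
from .geometry import ChamberGeometry
from .schedule import DAY_KINDS, LightSchedule, NIGHT_KINDS

__all__ = [
    "BinnedSeries",
    "CrossingEvents",
    "SleepBout",
    "frame_distances",
    "bin_activity",
    "group_mean",
    "group_median",
    "virtual_dam",
    "flag_dead_fly",
    "midline_band_occupancy",
    "bin_crossings",
    "sleep_bouts",
    "sleep_binned",
    "average_day",
    "day_night_totals",
    "compare_totals",
    "compare_hourly",
]

SLEEP_THRESHOLD_S = 300.0  # five minutes without a beam crossing


# ---------------------------------------------------------------------------
# containers


@dataclass
class BinnedSeries:
    """A per-fly metric on a regular time grid.

    ``bin_starts`` are experiment seconds; bins are contiguous,
    ``bin_minutes`` wide, and only complete bins are kept.
    """

    bin_minutes: float
    bin_starts: np.ndarray
    values: np.ndarray
    fly_id: str = "fly"
    metric: str = "distance_px"

    def __post_init__(self) -> None:
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_starts.shape != self.values.shape:
            raise ValueError("bin_starts and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def bin_seconds(self) -> float:
        return self.bin_minutes * 60.0


@dataclass
class CrossingEvents:
    """Frames at which a midline crossing completed, with their timestamps."""

    frames: np.ndarray
    fps: float
    n_frames: int  # length of the source recording, for span bookkeeping
    fly_id: str = "fly"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("crossing frames must be strictly increasing")
        if len(self.frames) > max(self.n_frames - 1, 0):
            raise ValueError("cannot have more crossings than frame transitions")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.fps


@dataclass(frozen=True)
class SleepBout:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# distance activity


def frame_distances(cleaned: CleanedSeries) -> np.ndarray:
    """Euclidean distance between consecutive cleaned positions (px).

    Length ``n - 1``; gaps in the frame index contribute the straight-line
    distance across the gap.  Fewer than two frames yields an empty result.
    """
    if len(cleaned) < 2:
        return np.array([], dtype=float)
    return np.hypot(np.diff(cleaned.x), np.diff(cleaned.y))


def bin_activity(
    distances: np.ndarray,
    frames: np.ndarray,
    fps: float,
    bin_minutes: float,
    t_start: float = 0.0,
    duration_s: float | None = None,
    fly_id: str = "fly",
) -> BinnedSeries:
    """Sum frame-to-frame distances into contiguous time bins.

    The interval between frames ``i`` and ``i+1`` is assigned to the bin
    containing frame ``i``'s timestamp.  The incomplete trailing bin is
    dropped, so the sum over bins equals the trajectory distance restricted
    to complete bins, exactly.
    """
    if fps <= 0 or bin_minutes <= 0:
        raise ValueError("fps and bin_minutes must be positive")
    frames = np.asarray(frames)
    if duration_s is None:
        duration_s = float(frames[-1] + 1) / fps if len(frames) else 0.0
    bin_s = bin_minutes * 60.0
    n_bins = int(math.floor((duration_s - t_start) / bin_s))
    if n_bins <= 0:
        return BinnedSeries(bin_minutes, np.array([]), np.array([]), fly_id=fly_id)
    t = frames[:-1] / fps  # timestamp of the leading frame of each interval
    which = np.floor((t - t_start) / bin_s).astype(int)
    ok = (which >= 0) & (which < n_bins)
    values = np.bincount(which[ok], weights=np.asarray(distances)[ok], minlength=n_bins)
    starts = t_start + bin_s * np.arange(n_bins)
    return BinnedSeries(bin_minutes, starts, values, fly_id=fly_id, metric="distance_px")


def _check_aligned(group: Sequence[BinnedSeries]) -> None:
    if not group:
        raise GridAlignmentError("empty group")
    ref = group[0]
    for b in group[1:]:
        if b.bin_minutes != ref.bin_minutes or not np.array_equal(b.bin_starts, ref.bin_starts):
            raise GridAlignmentError("flies do not share a common bin grid")


def _group_stat(group: Sequence[BinnedSeries], fn, name: str) -> BinnedSeries:
    _check_aligned(group)
    mat = np.vstack([b.values for b in group])
    return BinnedSeries(
        group[0].bin_minutes, group[0].bin_starts.copy(), fn(mat, axis=0),
        fly_id=name, metric=group[0].metric,
    )


def group_mean(group: Sequence[BinnedSeries]) -> BinnedSeries:
    """Element-wise mean across flies (grids must match)."""
    return _group_stat(group, np.mean, "group_mean")


def group_median(group: Sequence[BinnedSeries]) -> BinnedSeries:
    """Element-wise median across flies — the robust group trace used for plots."""
    return _group_stat(group, np.median, "group_median")


# ---------------------------------------------------------------------------
# virtual beam


def _held_sides(coord: np.ndarray, midline: float) -> np.ndarray:
    """Side of the midline per frame with hysteresis at exact hits.

    -1 below the midline, +1 above; a frame exactly on the midline keeps
    the previously held side (so grazing the beam never registers a
    crossing), and -1 if no side was ever held.
    """
    s = np.sign(coord - midline).astype(np.int8)
    if np.any(s == 0):
        # forward-fill the last non-zero side
        idx = np.arange(len(s))
        nz = np.where(s != 0, idx, -1)
        nz = np.maximum.accumulate(nz)
        filled = np.where(nz >= 0, s[np.maximum(nz, 0)], -1)
        s = filled.astype(np.int8)
    return s


def virtual_dam(cleaned: CleanedSeries, geom: ChamberGeometry | None = None) -> CrossingEvents:
    """Count crossings of a virtual beam at the chamber midline.

    A crossing completes at frame ``i+1`` when the held side changes
    between frames ``i`` and ``i+1``.  Runs of interpolated frames are
    constant-position, so they generate no internal crossings.
    """
    geom = geom or cleaned.geometry
    if len(cleaned) < 2:
        return CrossingEvents(np.array([], dtype=np.int64), cleaned.fps, len(cleaned),
                              fly_id=cleaned.fly_id)
    coord = np.asarray(geom.long_coord(cleaned.x, cleaned.y), dtype=float)
    s = _held_sides(coord, float(geom.midline))
    change = np.nonzero(np.diff(s) != 0)[0] + 1
    return CrossingEvents(cleaned.frames[change], cleaned.fps, len(cleaned),
                          fly_id=cleaned.fly_id)


def midline_band_occupancy(cleaned: CleanedSeries, half_width_px: float,
                           geom: ChamberGeometry | None = None) -> np.ndarray:
    """Alternative beam read-out: mask of frames within +/- half_width_px of the midline.

    Counting frames inside a midline band ("detections along the midline")
    rather than side changes; provided for comparison with the crossing
    statistic, which is the primary read-out.
    """
    geom = geom or cleaned.geometry
    coord = np.asarray(geom.long_coord(cleaned.x, cleaned.y), dtype=float)
    return np.abs(coord - geom.midline) <= half_width_px


def bin_crossings(
    events: CrossingEvents,
    bin_minutes: float,
    t_start: float = 0.0,
    duration_s: float | None = None,
) -> BinnedSeries:
    """Count crossing events per time bin (same bin conventions as bin_activity)."""
    if duration_s is None:
        duration_s = events.n_frames / events.fps
    bin_s = bin_minutes * 60.0
    n_bins = int(math.floor((duration_s - t_start) / bin_s))
    if n_bins <= 0:
        return BinnedSeries(bin_minutes, np.array([]), np.array([]),
                            fly_id=events.fly_id, metric="crossings")
    t = events.times
    which = np.floor((t - t_start) / bin_s).astype(int)
    ok = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[ok], minlength=n_bins).astype(float)
    starts = t_start + bin_s * np.arange(n_bins)
    return BinnedSeries(bin_minutes, starts, counts, fly_id=events.fly_id, metric="crossings")


# ---------------------------------------------------------------------------
# sleep


def flag_dead_fly(cleaned: CleanedSeries, window_s: float = 86400.0,
                  distance_threshold_px: float = 1.0) -> bool:
    """Heuristic death flag: no beam crossing and < 1 px total movement
    over the final ``window_s`` of the recording.

    Intended for optional exclusion from group aggregates; nothing in the
    pipeline applies it automatically.
    """
    t0 = max(0.0, cleaned.duration_s - window_s)
    sel = cleaned.times >= t0
    if sel.sum() < 2:
        return False
    sub = CleanedSeries(
        frames=cleaned.frames[sel], x=cleaned.x[sel], y=cleaned.y[sel],
        likelihood=cleaned.likelihood[sel],
        interpolated_mask=cleaned.interpolated_mask[sel],
        geometry=cleaned.geometry, fps=cleaned.fps, fly_id=cleaned.fly_id,
    )
    if frame_distances(sub).sum() >= distance_threshold_px:
        return False
    return len(virtual_dam(sub)) == 0


def sleep_bouts(
    events: CrossingEvents,
    span: tuple[float, float] | None = None,
    threshold_s: float = SLEEP_THRESHOLD_S,
) -> list[SleepBout]:
    """Extract sleep bouts: beam-quiescent intervals of at least ``threshold_s``.

    Every maximal interval without a crossing — including the edges of the
    recording span — of duration >= threshold (default 300 s, i.e. five
    consecutive minutes) is one bout covering that whole interval.
    """
    if span is None:
        span = (0.0, events.n_frames / events.fps)
    t0, t1 = span
    times = events.times
    times = times[(times >= t0) & (times <= t1)]
    edges = np.concatenate([[t0], times, [t1]])
    bouts = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a >= threshold_s:
            bouts.append(SleepBout(float(a), float(b)))
    return bouts


def sleep_binned(
    bouts: Sequence[SleepBout],
    bin_minutes: float,
    span: tuple[float, float],
    fly_id: str = "fly",
) -> BinnedSeries:
    """Minutes asleep per time bin: overlap of sleep bouts with each bin."""
    t0, t1 = span
    bin_s = bin_minutes * 60.0
    n_bins = int(math.floor((t1 - t0) / bin_s))
    starts = t0 + bin_s * np.arange(n_bins)
    minutes = np.zeros(n_bins)
    for bout in bouts:
        lo = np.maximum(starts, bout.start_s)
        hi = np.minimum(starts + bin_s, bout.end_s)
        minutes += np.clip(hi - lo, 0.0, None) / 60.0
    return BinnedSeries(bin_minutes, starts, minutes, fly_id=fly_id, metric="sleep_min")


# ---------------------------------------------------------------------------
# circadian summaries


def average_day(
    binned: BinnedSeries,
    schedule: LightSchedule,
    n_full_days: int = 2,
) -> BinnedSeries:
    """Average-day profile: per-ZT-bin mean over ``n_full_days`` complete cycles.

    Bins are re-anchored at the first ZT0 at or after the start of the
    binned record; the profile value at ZT bin ``h`` is the mean over days
    of the fly's values in that ZT bin.
    """
    bin_s = binned.bin_seconds
    per_day = 24.0 * 3600.0 / bin_s
    if abs(per_day - round(per_day)) > 1e-9:
        raise ValueError("bin width must divide 24 h for an average day")
    per_day = int(round(per_day))
    if len(binned) == 0:
        raise InsufficientDaysError("empty binned series")
    # first bin whose start is at ZT0 (modulo 24 h)
    zt = np.array([schedule.zt_of(t) for t in binned.bin_starts])
    anchors = np.nonzero(np.isclose(zt, 0.0, atol=1e-6) | np.isclose(zt, 24.0, atol=1e-6))[0]
    if len(anchors) == 0:
        raise InsufficientDaysError("record contains no ZT0-aligned bin")
    a0 = int(anchors[0])
    needed = n_full_days * per_day
    if len(binned) - a0 < needed:
        raise InsufficientDaysError(
            f"need {n_full_days} complete days ({needed} bins) from ZT0, "
            f"have {len(binned) - a0}"
        )
    block = binned.values[a0:a0 + needed].reshape(n_full_days, per_day)
    profile = block.mean(axis=0)
    zt_starts = bin_s * np.arange(per_day)  # seconds since ZT0
    return BinnedSeries(binned.bin_minutes, zt_starts, profile,
                        fly_id=binned.fly_id, metric=binned.metric + "_avg_day")


def day_night_totals(binned: BinnedSeries, schedule: LightSchedule) -> dict:
    """Per-fly totals over all complete 12 h day and night phases.

    A bin belongs to the phase containing its start time.  Only phases
    fully covered by the binned record contribute.
    """
    day_total = 0.0
    night_total = 0.0
    t_end = binned.bin_starts[-1] + binned.bin_seconds if len(binned) else 0.0
    for ph in schedule.phases:
        if ph.start_s < binned.bin_starts[0] - 1e-9 or ph.end_s > t_end + 1e-9:
            continue  # phase not fully recorded
        sel = (binned.bin_starts >= ph.start_s) & (binned.bin_starts < ph.end_s)
        total = float(binned.values[sel].sum())
        if ph.kind in DAY_KINDS:
            day_total += total
        elif ph.kind in NIGHT_KINDS:
            night_total += total
    return {"fly_id": binned.fly_id, "day": day_total, "night": night_total}


def compare_totals(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> tuple[float, float]:
    """Two-sided t-test between two groups of per-fly totals.

    Welch (unequal variances) by default; ``equal_var=True`` selects the
    classical pooled-variance test.

    Raises
    ------
    StatisticUndefinedError
        Group smaller than two flies, or zero variance in both groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatisticUndefinedError("need at least two flies per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if math.isnan(t) or math.isnan(p):
        raise StatisticUndefinedError("test statistic undefined (zero variance in both groups)")
    return t, p


@dataclass
class HourlyComparison:
    """Per-ZT-hour two-group comparison with FDR-adjusted discovery flags."""

    u_stats: np.ndarray
    pvalues: np.ndarray
    pvalues_adjusted: np.ndarray
    discovery: np.ndarray           # True where FDR-adjusted p <= q
    higher_group: np.ndarray        # 'A', 'B' or '' per hour (only meaningful at discoveries)
    q: float
    method: str


def compare_hourly(
    group_a: np.ndarray,
    group_b: np.ndarray,
    q: float = 0.05,
    method: str = "fdr_bh",
) -> HourlyComparison:
    """Hour-by-hour Mann-Whitney comparison of two groups' average days.

    ``group_a``/``group_b`` are (n_flies, n_hours) matrices of per-fly
    average-day values.  Each hour gets a two-sided Mann-Whitney U test;
    multiplicity is controlled across hours by Benjamini-Hochberg FDR at
    level ``q`` (``method="fdr_tsbky"`` selects the two-stage procedure).
    An hour with an adjusted p-value <= q is a "discovery", and the group
    with the higher median is recorded for it.
    """
    from statsmodels.stats.multitest import multipletests

    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise GridAlignmentError("groups must cover the same hourly bins")
    n_hours = a.shape[1]
    u = np.empty(n_hours)
    p = np.empty(n_hours)
    for h in range(n_hours):
        xa, xb = a[:, h], b[:, h]
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            # all observations tied: no evidence either way
            u[h], p[h] = len(xa) * len(xb) / 2.0, 1.0
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
        u[h], p[h] = float(res.statistic), float(res.pvalue)
    p = np.nan_to_num(p, nan=1.0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=method)
    # a single observation per group can never be a discovery
    if a.shape[0] < 2 or b.shape[0] < 2:
        reject = np.zeros(n_hours, dtype=bool)
    higher = np.array(
        ["A" if np.median(a[:, h]) > np.median(b[:, h])
         else ("B" if np.median(b[:, h]) > np.median(a[:, h]) else "")
         for h in range(n_hours)],
        dtype=object,
    )
    return HourlyComparison(u, p, p_adj, reject, higher, q=q, method=method)
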