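"""Positional analyses: where the fly spends its time.

Positions are first averaged within each second, then within the chosen
time bin — a two-level averaging that suppresses tracking jitter without
hiding slow relocations (e.g. a mated female settling on the food).
Occupancy is summarised either as a 2-D heatmap over the chamber or as a
longitudinal histogram along the long axis, the read-out used by the
two-food place-preference assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from .activity import compare_totals
from .cleaning import CleanedSeries
from .errors import GridAlignmentError, StatisticUndefinedError
from .geometry import ChamberGeometry

__all__ = [
    "PositionSeries",
    "PreferenceHistogram",
    "position_per_second",
    "position_binned",
    "group_position",
    "occupancy_heatmap",
    "preference_histogram",
    "food_bin_indices",
    "preference_test",
]


@dataclass
class PositionSeries:
    """(x, y) position on a regular time grid (seconds or bins)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fly_id: str = "fly"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PreferenceHistogram:
    """Occupancy fractions in equal bins along the chamber's long axis."""

    edges: np.ndarray        # n_bins + 1 strictly increasing pixel edges
    fractions: np.ndarray    # per-bin fraction of frames, sums to 1
    fly_id: str = "fly"
    food_bins: dict | None = None   # label -> bin index, when foods are configured

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.edges) != len(self.fractions) + 1:
            raise ValueError("need n_bins + 1 edges")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.fractions)


def position_per_second(cleaned: CleanedSeries) -> PositionSeries:
    """Average position within each second of the recording.

    Second ``s`` holds the mean of all frames with timestamp in
    ``[s, s+1)``; seconds with no frames inherit the previous second's
    value, keeping the trace on a uniform grid.
    """
    if len(cleaned) == 0:
        return PositionSeries(np.array([]), np.array([]), np.array([]), fly_id=cleaned.fly_id)
    secs = np.floor(cleaned.times).astype(int)
    s0, s1 = int(secs[0]), int(secs[-1])
    n = s1 - s0 + 1
    counts = np.bincount(secs - s0, minlength=n)
    sx = np.bincount(secs - s0, weights=cleaned.x, minlength=n)
    sy = np.bincount(secs - s0, weights=cleaned.y, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = sx / counts
        my = sy / counts
    # forward-fill empty seconds from the previous second
    have = counts > 0
    idx = np.where(have, np.arange(n), -1)
    idx = np.maximum.accumulate(idx)
    mx = mx[np.maximum(idx, 0)]
    my = my[np.maximum(idx, 0)]
    return PositionSeries(np.arange(s0, s1 + 1, dtype=float), mx, my, fly_id=cleaned.fly_id)


def position_binned(per_second: PositionSeries, bin_minutes: float,
                    t_start: float = 0.0) -> PositionSeries:
    """Average the per-second trace within each complete time bin."""
    if len(per_second) == 0:
        return PositionSeries(np.array([]), np.array([]), np.array([]),
                              fly_id=per_second.fly_id)
    bin_s = bin_minutes * 60.0
    t_end = per_second.times[-1] + 1.0
    n_bins = int(math.floor((t_end - t_start) / bin_s))
    which = np.floor((per_second.times - t_start) / bin_s).astype(int)
    ok = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[ok], minlength=n_bins)
    bx = np.bincount(which[ok], weights=per_second.x[ok], minlength=n_bins)
    by = np.bincount(which[ok], weights=per_second.y[ok], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        bx, by = bx / counts, by / counts
    starts = t_start + bin_s * np.arange(n_bins)
    return PositionSeries(starts, bx, by, fly_id=per_second.fly_id)


def group_position(traces: Sequence[PositionSeries]) -> PositionSeries:
    """Element-wise mean trace across flies (time grids must match)."""
    if not traces:
        raise GridAlignmentError("empty group")
    ref = traces[0]
    for t in traces[1:]:
        if not np.array_equal(t.times, ref.times):
            raise GridAlignmentError("flies do not share a common time grid")
    return PositionSeries(
        ref.times.copy(),
        np.mean([t.x for t in traces], axis=0),
        np.mean([t.y for t in traces], axis=0),
        fly_id="group_mean",
    )


def _cell_index(v: np.ndarray, lo: float, hi: float, n: int) -> np.ndarray:
    """Half-open equal-width cell index, clipped so v == hi lands in the last cell."""
    idx = np.floor((np.asarray(v) - lo) / (hi - lo) * n).astype(int)
    return np.clip(idx, 0, n - 1)


def occupancy_heatmap(
    cleaned: CleanedSeries,
    geom: ChamberGeometry | None = None,
    grid_nx: int = 10,
    grid_ny: int = 10,
    exclude_interpolated: bool = False,
) -> np.ndarray:
    """2-D occupancy fractions on a grid over the chamber, shape (ny, nx), sums to 1.

    Interpolated frames count at their interpolated position by default
    (the cleaning stage runs first in the pipeline); set
    ``exclude_interpolated`` to drop them.
    """
    geom = geom or cleaned.geometry
    if grid_nx < 1 or grid_ny < 1:
        raise ValueError("grid must be at least 1x1")
    x, y = cleaned.x, cleaned.y
    if exclude_interpolated:
        keep = ~cleaned.interpolated_mask
        x, y = x[keep], y[keep]
    if len(x) == 0:
        return np.zeros((grid_ny, grid_nx))
    ix = _cell_index(x, geom.x_min, geom.x_max, grid_nx)
    iy = _cell_index(y, geom.y_min, geom.y_max, grid_ny)
    counts = np.bincount(iy * grid_nx + ix, minlength=grid_nx * grid_ny)
    return counts.reshape(grid_ny, grid_nx) / len(x)


def food_bin_indices(geom: ChamberGeometry, n_bins: int = 10) -> dict:
    """Map each food label to the longitudinal bin closest to it.

    "Closest" is the single bin abutting the chamber wall nearest the food
    region: index 0 for a food at the low end of the long axis, index
    ``n_bins - 1`` at the high end.
    """
    lo, hi = geom.long_interval
    centre = 0.5 * (lo + hi)
    return {
        r.label: (0 if r.center < centre else n_bins - 1)
        for r in geom.food_regions
    }


def preference_histogram(
    cleaned: CleanedSeries,
    geom: ChamberGeometry | None = None,
    n_bins: int = 10,
    exclude_interpolated: bool = False,
) -> PreferenceHistogram:
    """Occupancy fractions in ``n_bins`` equal bins along the long axis.

    With the standard two-food chamber and 10 bins this gives ~5 mm bins;
    food labels, when configured, are mapped to their nearest bin.
    """
    geom = geom or cleaned.geometry
    lo, hi = geom.long_interval
    coord = np.asarray(geom.long_coord(cleaned.x, cleaned.y), dtype=float)
    if exclude_interpolated:
        coord = coord[~cleaned.interpolated_mask]
    if len(coord) == 0:
        raise StatisticUndefinedError("no frames to build a preference histogram from")
    idx = _cell_index(coord, lo, hi, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.linspace(lo, hi, n_bins + 1)
    return PreferenceHistogram(
        edges, counts / len(coord), fly_id=cleaned.fly_id,
        food_bins=food_bin_indices(geom, n_bins) if geom.food_regions else None,
    )


def preference_test(
    group_a: Sequence[PreferenceHistogram],
    group_b: Sequence[PreferenceHistogram],
    food_bins: dict | None = None,
) -> dict:
    """Welch t-test of food-adjacent-bin occupancy between two groups.

    For each food's nearest bin, the per-fly occupancy fractions of the two
    groups are compared with a two-sided Welch t-test.  Returns
    ``{label: (t, p)}``.

    Raises
    ------
    StatisticUndefinedError
        Fewer than two flies in either group.
    """
    if food_bins is None:
        if not group_a or group_a[0].food_bins is None:
            raise StatisticUndefinedError("no food bins configured")
        food_bins = group_a[0].food_bins
    if len(group_a) < 2 or len(group_b) < 2:
        raise StatisticUndefinedError("need at least two flies per group")
    out = {}
    for label, b in food_bins.items():
        fa = np.array([h.fractions[b] for h in group_a])
        fb = np.array([h.fractions[b] for h in group_b])
        out[label] = compare_totals(fa, fb, equal_var=False)
    return out
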