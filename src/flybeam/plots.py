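"""Figure generation.

Styling follows the field's conventions: light phases shaded yellow, dark
phases grey, subjective day (constant darkness) light grey.  Every figure
has a CSV twin written by the pipeline, so no result exists only as
pixels.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .activity import BinnedSeries
from .geometry import ChamberGeometry
from .position import PositionSeries, PreferenceHistogram
from .schedule import LightSchedule

PHASE_COLORS = {
    "L": "#fff3b0",
    "D": "#c8c8c8",
    "subjective_day": "#ebebeb",
    "subjective_night": "#c8c8c8",
}


def _shade_phases(ax, schedule: LightSchedule, unit: float = 3600.0) -> None:
    for ph in schedule.phases:
        ax.axvspan(ph.start_s / unit, ph.end_s / unit,
                   color=PHASE_COLORS.get(ph.kind, "white"), zorder=0, lw=0)


def plot_group_trace(group: Sequence[BinnedSeries], mean: BinnedSeries,
                     schedule: LightSchedule, path, ylabel: str = "distance (px)") -> None:
    """Group activity trace: thin per-fly lines, thick group line, L/D shading."""
    fig, ax = plt.subplots(figsize=(10, 3))
    _shade_phases(ax, schedule)
    for b in group:
        ax.plot(b.bin_starts / 3600.0, b.values, color="0.5", lw=0.4, alpha=0.5)
    ax.plot(mean.bin_starts / 3600.0, mean.values, color="C0", lw=1.8)
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    ax.set_xlim(schedule.start_s / 3600.0, schedule.end_s / 3600.0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_average_day(profile: BinnedSeries, path, ylabel: str = "distance (px)") -> None:
    """Average-day bar profile against ZT, lights-off half shaded."""
    fig, ax = plt.subplots(figsize=(6, 3))
    zt = profile.bin_starts / 3600.0
    width = profile.bin_minutes / 60.0
    ax.axvspan(12, 24, color=PHASE_COLORS["D"], zorder=0, lw=0)
    ax.bar(zt, profile.values, width=width, align="edge", color="C0")
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel(ylabel)
    ax.set_xlim(0, 24)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_day_night_boxes(groups: dict[str, dict[str, np.ndarray]], path,
                         ylabel: str = "total distance (px)") -> None:
    """Day/night total boxplots per group (e.g. virgin vs mated)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels, data = [], []
    for gname, phases in groups.items():
        for phase in ("day", "night"):
            labels.append(f"{gname}\n{phase}")
            data.append(np.asarray(phases[phase]))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(hm: np.ndarray, geom: ChamberGeometry, path,
                 food_side_label: str | None = None) -> None:
    """Occupancy heatmap; the food edge, when labelled, is drawn at the bottom."""
    fig, ax = plt.subplots(figsize=(3, 5))
    ax.imshow(hm, origin="upper", aspect="auto", cmap="viridis")
    ax.set_xticks([])
    ax.set_yticks([])
    if food_side_label:
        ax.set_xlabel(food_side_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_position_trace(traces: Sequence[PositionSeries], mean: PositionSeries,
                        geom: ChamberGeometry, schedule: LightSchedule, path,
                        food_low: str | None = None, food_high: str | None = None) -> None:
    """Long-axis position over time: thin per-fly lines, thick group mean."""
    fig, ax = plt.subplots(figsize=(10, 3))
    _shade_phases(ax, schedule)
    for tr in traces:
        ax.plot(tr.times / 3600.0, geom.long_coord(tr.x, tr.y), color="0.5",
                lw=0.4, alpha=0.5)
    ax.plot(mean.times / 3600.0, geom.long_coord(mean.x, mean.y), color="C0", lw=1.8)
    lo, hi = geom.long_interval
    ax.set_ylim(hi, lo)  # food end (high coordinate) at the bottom of the chart
    if food_high:
        ax.text(0.01, 0.02, food_high, transform=ax.transAxes, va="bottom")
    if food_low:
        ax.text(0.01, 0.98, food_low, transform=ax.transAxes, va="top")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("long-axis position (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_preference_histogram(groups: dict[str, Sequence[PreferenceHistogram]],
                              path, food_labels: dict | None = None) -> None:
    """Mean longitudinal occupancy histogram per group, food bins annotated."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (gname, hists) in enumerate(groups.items()):
        mat = np.vstack([h.fractions for h in hists])
        n_bins = mat.shape[1]
        centers = np.arange(n_bins)
        ax.barh(centers + 0.4 * i - 0.2, mat.mean(axis=0), height=0.35,
                label=gname, color=f"C{i}")
    ax.invert_yaxis()
    if food_labels:
        for label, b in food_labels.items():
            ax.annotate(label, xy=(0.98, b), xycoords=("axes fraction", "data"),
                        ha="right", va="center", fontsize=8)
    ax.set_xlabel("occupancy fraction")
    ax.set_ylabel("longitudinal bin")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
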