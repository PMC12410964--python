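"""Experiment configuration: arena, chambers, light schedule, groups.

A single YAML file describes everything the analysis needs besides the
tracking tables themselves: the camera frame and crop grid, per-chamber
geometry overrides (midline, food regions, mm/px), the frame rate, the
light schedule, and the mapping of chamber ids to experimental groups.
The file round-trips losslessly through :func:`load_config` /
:func:`save_config`.

Example::

    fps: 5
    frame: {width: 1920, height: 1080}
    grid: {rows: 4, cols: 8, margin_x: 0, margin_y: 0, gap_x: 0, gap_y: 0}
    likelihood_floor: 0.9
    chamber:
      x_min: 0.0
      y_min: 0.0
      x_max: 150.0
      y_max: 230.0
      midline: 115.0
      long_axis: vertical
      mm_per_px: 0.1
      food_regions:
        - {label: food, start: 180.0, end: 230.0}
    schedule:
      zt0: 0.0
      phases:
        - {kind: L, hours: 12}
        - {kind: D, hours: 12}
    groups:
      virgin: [c00, c01]
      mated: [c02, c03]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .geometry import ArenaLayout, ChamberGeometry, FoodRegion
from .schedule import LightSchedule


@dataclass
class ExperimentConfig:
    fps: float = 5.0
    likelihood_floor: float = 0.9
    layout: ArenaLayout | None = None
    chamber: ChamberGeometry | None = None
    chamber_overrides: dict[str, ChamberGeometry] = field(default_factory=dict)
    schedule: LightSchedule | None = None
    groups: dict[str, list[str]] = field(default_factory=dict)
    bin_minutes: float = 10.0

    def chamber_for(self, chamber_id: str) -> ChamberGeometry | None:
        return self.chamber_overrides.get(chamber_id, self.chamber)


def _geom_to_dict(g: ChamberGeometry) -> dict:
    d = {
        "x_min": g.x_min, "y_min": g.y_min, "x_max": g.x_max, "y_max": g.y_max,
        "long_axis": g.long_axis, "midline": g.midline,
    }
    if g.mm_per_px is not None:
        d["mm_per_px"] = g.mm_per_px
    if g.food_regions:
        d["food_regions"] = [
            {"label": r.label, "start": r.start, "end": r.end} for r in g.food_regions
        ]
    return d


def _geom_from_dict(d: dict) -> ChamberGeometry:
    try:
        regions = tuple(
            FoodRegion(r["label"], float(r["start"]), float(r["end"]))
            for r in d.get("food_regions", [])
        )
        return ChamberGeometry(
            x_min=float(d["x_min"]), y_min=float(d["y_min"]),
            x_max=float(d["x_max"]), y_max=float(d["y_max"]),
            long_axis=d.get("long_axis"), midline=d.get("midline"),
            food_regions=regions,
            mm_per_px=d.get("mm_per_px"),
        )
    except KeyError as e:
        raise ConfigError(f"chamber geometry missing key {e}") from e


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d: dict = {"fps": cfg.fps, "likelihood_floor": cfg.likelihood_floor,
               "bin_minutes": cfg.bin_minutes}
    if cfg.layout is not None:
        la = cfg.layout
        d["frame"] = {"width": la.frame_width, "height": la.frame_height}
        d["grid"] = {"rows": la.rows, "cols": la.cols,
                     "margin_x": la.margin_x, "margin_y": la.margin_y,
                     "gap_x": la.gap_x, "gap_y": la.gap_y}
    if cfg.chamber is not None:
        d["chamber"] = _geom_to_dict(cfg.chamber)
    if cfg.chamber_overrides:
        d["chamber_overrides"] = {
            cid: _geom_to_dict(g) for cid, g in cfg.chamber_overrides.items()
        }
    if cfg.schedule is not None:
        d["schedule"] = cfg.schedule.to_dict()
    if cfg.groups:
        d["groups"] = {k: list(v) for k, v in cfg.groups.items()}
    return d


def config_from_dict(d: dict) -> ExperimentConfig:
    layout = None
    if "frame" in d and "grid" in d:
        layout = ArenaLayout(
            frame_width=int(d["frame"]["width"]), frame_height=int(d["frame"]["height"]),
            rows=int(d["grid"]["rows"]), cols=int(d["grid"]["cols"]),
            margin_x=int(d["grid"].get("margin_x", 0)), margin_y=int(d["grid"].get("margin_y", 0)),
            gap_x=int(d["grid"].get("gap_x", 0)), gap_y=int(d["grid"].get("gap_y", 0)),
        )
    return ExperimentConfig(
        fps=float(d.get("fps", 5.0)),
        likelihood_floor=float(d.get("likelihood_floor", 0.9)),
        bin_minutes=float(d.get("bin_minutes", 10.0)),
        layout=layout,
        chamber=_geom_from_dict(d["chamber"]) if "chamber" in d else None,
        chamber_overrides={
            cid: _geom_from_dict(g) for cid, g in d.get("chamber_overrides", {}).items()
        },
        schedule=LightSchedule.from_dict(d["schedule"]) if "schedule" in d else None,
        groups={k: list(v) for k, v in d.get("groups", {}).items()},
    )


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return config_from_dict(d)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
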