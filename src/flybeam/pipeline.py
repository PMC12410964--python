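"""End-to-end orchestration: clean every chamber, compute metrics, write outputs.

The pipeline is deterministic given its inputs and configuration (all
statistics use exact or asymptotic formulas — no resampling), tolerates
per-chamber failures (a corrupt table is logged and skipped, the rest of
the run continues), and emits a run manifest so every output file is
traceable to the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import (
    average_day,
    bin_activity,
    bin_crossings,
    compare_hourly,
    compare_totals,
    day_night_totals,
    frame_distances,
    group_mean,
    group_median,
    sleep_binned,
    sleep_bouts,
    virtual_dam,
)
from .cleaning import clean_series
from .config import ExperimentConfig
from .errors import FlybeamError
from .position import (
    position_binned,
    position_per_second,
    preference_histogram,
    preference_test,
)
from .tracking_io import read_tracking_csv, write_tracking_csv

log = logging.getLogger("flybeam")


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline run's outputs."""

    config_hash: str
    inputs: list[str]
    parameters: dict
    version: str = ""
    timestamp: str = ""
    succeeded: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)


def _hash_config(cfg: ExperimentConfig) -> str:
    from .config import config_to_dict

    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _binned_to_tidy(binned, schedule, fly_id):
    zt = [schedule.zt_of(t) if schedule else np.nan for t in binned.bin_starts]
    phase = [schedule.phase_at(min(t, np.nextafter(schedule.end_s, -np.inf))).kind
             if schedule else "" for t in binned.bin_starts]
    return pd.DataFrame({
        "fly_id": fly_id,
        "bin_start_s": binned.bin_starts,
        "zt_h": zt,
        "phase": phase,
        "value": binned.values,
    })


def run_pipeline(
    cfg: ExperimentConfig,
    inputs: dict[str, Path],
    out_dir: Path,
    bin_minutes: float | None = None,
    make_plots: bool = True,
) -> RunManifest:
    """Run clean -> activity -> virtual beam -> sleep -> position on every chamber.

    ``inputs`` maps chamber ids to tracking CSV paths.  Outputs (cleaned
    CSVs, tidy metric CSVs, group comparisons, plots, manifest) land in
    ``out_dir``.  One corrupt chamber does not abort the run: it is
    recorded in the manifest's ``failed`` map and skipped.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bin_minutes = bin_minutes or cfg.bin_minutes
    schedule = cfg.schedule

    manifest = RunManifest(
        config_hash=_hash_config(cfg),
        inputs=[str(p) for p in inputs.values()],
        parameters={"bin_minutes": bin_minutes, "fps": cfg.fps,
                    "likelihood_floor": cfg.likelihood_floor},
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    per_fly: dict[str, dict] = {}
    clean_reports = []
    for chamber_id, path in inputs.items():
        try:
            series = read_tracking_csv(path, fps=cfg.fps, chamber_id=chamber_id,
                                       likelihood_floor=cfg.likelihood_floor)
            cleaned, report = clean_series(series, geometry=cfg.chamber_for(chamber_id),
                                           likelihood_floor=cfg.likelihood_floor)
            clean_reports.append(report)
            write_tracking_csv(
                _cleaned_as_series(cleaned, series), out_dir / f"{chamber_id}_cleaned.csv"
            )

            d = frame_distances(cleaned)
            dist = bin_activity(d, cleaned.frames, cfg.fps, bin_minutes,
                                duration_s=cleaned.duration_s, fly_id=chamber_id)
            events = virtual_dam(cleaned)
            cross = bin_crossings(events, bin_minutes)
            bouts = sleep_bouts(events)
            sleep = sleep_binned(bouts, bin_minutes, (0.0, cleaned.duration_s),
                                 fly_id=chamber_id)
            pos = position_binned(position_per_second(cleaned), bin_minutes)
            per_fly[chamber_id] = {
                "distance": dist, "crossings": cross, "sleep": sleep,
                "position": pos, "cleaned": cleaned,
            }
            log.info("chamber %s: %d frames, %d interpolated, %d crossings",
                     chamber_id, len(cleaned), cleaned.n_interpolated, len(events))
            manifest.succeeded.append(chamber_id)
        except (FlybeamError, OSError) as e:
            log.error("chamber %s failed: %s", chamber_id, e)
            manifest.failed[chamber_id] = str(e)

    pd.DataFrame(clean_reports).to_csv(out_dir / "cleaning_report.csv", index=False)

    for metric in ("distance", "crossings", "sleep"):
        tidy = pd.concat(
            [_binned_to_tidy(v[metric], schedule, cid) for cid, v in per_fly.items()],
            ignore_index=True,
        ) if per_fly else pd.DataFrame()
        tidy.to_csv(out_dir / f"{metric}.csv", index=False)

    _group_analyses(cfg, per_fly, out_dir, bin_minutes, make_plots)
    manifest.write(out_dir / "manifest.json")
    return manifest


def _cleaned_as_series(cleaned, original):
    from .tracking_io import TrackingSeries

    return TrackingSeries(
        frames=cleaned.frames, x=cleaned.x, y=cleaned.y,
        likelihood=cleaned.likelihood, fps=cleaned.fps,
        fly_id=original.fly_id, chamber_id=original.chamber_id,
        scorer=original.scorer, bodypart=original.bodypart,
    )


def _group_analyses(cfg, per_fly, out_dir, bin_minutes, make_plots) -> None:
    schedule = cfg.schedule
    groups = cfg.groups or ({"all": list(per_fly)} if per_fly else {})
    groups = {g: [c for c in cids if c in per_fly] for g, cids in groups.items()}
    groups = {g: cids for g, cids in groups.items() if cids}
    if not groups:
        return

    # group traces + day/night totals
    totals = {}
    rows = []
    for gname, cids in groups.items():
        binned = [per_fly[c]["distance"] for c in cids]
        gmean = group_mean(binned)
        gmed = group_median(binned)
        if schedule is not None:
            tot = [day_night_totals(b, schedule) for b in binned]
            totals[gname] = {
                "day": np.array([t["day"] for t in tot]),
                "night": np.array([t["night"] for t in tot]),
            }
            rows.extend({"group": gname, **t} for t in tot)
        if make_plots and schedule is not None:
            from . import plots

            plots.plot_group_trace(binned, gmed, schedule,
                                   out_dir / f"trace_{gname}.png")
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "day_night_totals.csv", index=False)

    # pairwise group statistics
    stats_rows = []
    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if a in totals and b in totals:
                for phase in ("day", "night"):
                    try:
                        t, p = compare_totals(totals[a][phase], totals[b][phase])
                        stats_rows.append({"group_a": a, "group_b": b,
                                           "phase": phase, "t": t, "p": p})
                    except FlybeamError as e:
                        log.warning("%s vs %s (%s): %s", a, b, phase, e)
    if stats_rows:
        pd.DataFrame(stats_rows).to_csv(out_dir / "day_night_tests.csv", index=False)

    # hourly average-day comparison for the first two groups
    if schedule is not None and len(names) >= 2 and bin_minutes <= 60:
        try:
            profs = {}
            for gname in names[:2]:
                mats = []
                for c in groups[gname]:
                    hourly = _rebin(per_fly[c]["distance"], 60.0)
                    mats.append(average_day(hourly, schedule).values)
                profs[gname] = np.vstack(mats)
            hc = compare_hourly(profs[names[0]], profs[names[1]])
            pd.DataFrame({
                "zt_hour": np.arange(profs[names[0]].shape[1]),
                "u": hc.u_stats, "p": hc.pvalues, "p_adj": hc.pvalues_adjusted,
                "discovery": hc.discovery, "higher": hc.higher_group,
            }).to_csv(out_dir / "hourly_tests.csv", index=False)
        except FlybeamError as e:
            log.warning("hourly comparison skipped: %s", e)

    # place preference, when food regions are configured
    geoms = {c: per_fly[c]["cleaned"].geometry for c in per_fly}
    if any(g.food_regions for g in geoms.values()):
        hists = {g: [preference_histogram(per_fly[c]["cleaned"]) for c in cids
                     if geoms[c].food_regions]
                 for g, cids in groups.items()}
        hists = {g: h for g, h in hists.items() if h}
        rows = []
        for gname, hs in hists.items():
            for h in hs:
                for b, f in enumerate(h.fractions):
                    rows.append({"group": gname, "fly_id": h.fly_id,
                                 "bin": b, "fraction": f})
        pd.DataFrame(rows).to_csv(out_dir / "preference.csv", index=False)
        if len(hists) >= 2:
            a, b = list(hists)[:2]
            try:
                tests = preference_test(hists[a], hists[b])
                pd.DataFrame(
                    [{"food": k, "t": t, "p": p} for k, (t, p) in tests.items()]
                ).to_csv(out_dir / "preference_tests.csv", index=False)
            except FlybeamError as e:
                log.warning("preference test skipped: %s", e)


def _rebin(binned, target_minutes: float):
    """Aggregate a finer binned series into coarser bins by summation."""
    from .activity import BinnedSeries

    ratio = target_minutes / binned.bin_minutes
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target bin width must be a multiple of the source width")
    k = int(round(ratio))
    n = (len(binned) // k) * k
    vals = binned.values[:n].reshape(-1, k).sum(axis=1)
    starts = binned.bin_starts[:n:k]
    return BinnedSeries(target_minutes, starts, vals, fly_id=binned.fly_id,
                        metric=binned.metric)
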