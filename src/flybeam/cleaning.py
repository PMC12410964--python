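"""Misdetection control for tracked trajectories.

Trackers occasionally place the fly outside its chamber, usually with low
confidence.  Cleaning is a three-step procedure:

1. identify the limits of the chamber (from the data, unless the caller
   supplies a geometry);
2. flag the frames where the fly is detected outside the chamber, has low
   likelihood, or is missing;
3. replace flagged coordinates by the average position of the nearest
   preceding and following in-chamber detections.

Step 3's default reading is the unweighted coordinate-wise midpoint: a run
of consecutive flagged frames all receive the same midpoint, so the run
contributes exactly zero distance — a conservative choice that never
invents motion.  Time-weighted linear interpolation is available as an
optional mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGeometryError,
    GeometryInferenceError,
    UnrecoverableSeriesError,
)
from .geometry import ChamberGeometry
from .tracking_io import TrackingSeries

__all__ = [
    "CleanedSeries",
    "infer_chamber_limits",
    "flag_out_of_bounds",
    "interpolate_out_of_bounds",
    "clean_series",
]

DEFAULT_LIKELIHOOD_FLOOR = 0.9


@dataclass
class CleanedSeries:
    """A tracking series whose positions all lie inside ``geometry``.

    ``interpolated_mask`` marks the frames whose coordinates were replaced.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    interpolated_mask: np.ndarray
    geometry: ChamberGeometry
    fps: float = 5.0
    fly_id: str = "fly"
    chamber_id: str = "c00"

    def __post_init__(self) -> None:
        if len(self.interpolated_mask) != len(self.frames):
            raise ValueError("mask length must equal record count")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames / self.fps

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.frames[-1] + 1) / self.fps

    @property
    def n_interpolated(self) -> int:
        return int(self.interpolated_mask.sum())


def infer_chamber_limits(
    series: TrackingSeries,
    likelihood_floor: float = DEFAULT_LIKELIHOOD_FLOOR,
    lo_q: float = 0.001,
    hi_q: float = 0.999,
    pad: float = 2.0,
    min_detections: int = 100,
    min_extent: float = 5.0,
) -> ChamberGeometry:
    """Infer the chamber rectangle from the cloud of confident detections.

    Over a multi-hour recording the fly visits the whole chamber, so robust
    per-axis quantiles of the high-likelihood positions (plus a small pad)
    recover the walls while rejecting rare far-out misdetections.  The
    midline is placed at the centre of the long axis.

    Raises
    ------
    GeometryInferenceError
        Fewer than ``min_detections`` confident detections — the caller
        must supply a geometry instead.
    DegenerateGeometryError
        Inferred extent below ``min_extent`` px on either axis.
    """
    ok = (series.likelihood >= likelihood_floor) & np.isfinite(series.x) & np.isfinite(series.y)
    n = int(ok.sum())
    if n < min_detections:
        raise GeometryInferenceError(
            f"only {n} detections with likelihood >= {likelihood_floor}; "
            f"need >= {min_detections} to infer chamber limits"
        )
    xs, ys = series.x[ok], series.y[ok]
    x_lo, x_hi = np.quantile(xs, [lo_q, hi_q])
    y_lo, y_hi = np.quantile(ys, [lo_q, hi_q])
    x_min, x_max = x_lo - pad, x_hi + pad
    y_min, y_max = y_lo - pad, y_hi + pad
    if (x_max - x_min) < min_extent or (y_max - y_min) < min_extent:
        raise DegenerateGeometryError(
            f"inferred extent {x_max - x_min:.1f}x{y_max - y_min:.1f} px is degenerate"
        )
    return ChamberGeometry(x_min=x_min, y_min=y_min, x_max=x_max, y_max=y_max)


def flag_out_of_bounds(
    series: TrackingSeries,
    geom: ChamberGeometry,
    likelihood_floor: float = DEFAULT_LIKELIHOOD_FLOOR,
) -> np.ndarray:
    """Boolean mask of frames to interpolate.

    True where the detection is outside the chamber, below the likelihood
    floor, or missing (non-finite coordinates).  ``likelihood_floor=0``
    disables confidence filtering.
    """
    finite = np.isfinite(series.x) & np.isfinite(series.y)
    inside = np.zeros(len(series), dtype=bool)
    with np.errstate(invalid="ignore"):
        inside[finite] = (
            (series.x[finite] >= geom.x_min)
            & (series.x[finite] < geom.x_max)
            & (series.y[finite] >= geom.y_min)
            & (series.y[finite] < geom.y_max)
        )
        low = series.likelihood < likelihood_floor
    return (~inside) | low | np.isnan(series.likelihood)


def interpolate_out_of_bounds(
    series: TrackingSeries,
    mask: np.ndarray,
    geometry: ChamberGeometry,
    mode: str = "midpoint",
) -> CleanedSeries:
    """Replace flagged frames by the average of flanking good detections.

    mode="midpoint" (default): every frame of a flagged run receives the
    unweighted midpoint of the nearest preceding and following unflagged
    positions.  mode="linear": time-weighted linear interpolation between
    the same two anchors.  Leading (trailing) runs copy the first (last)
    unflagged position.  Unflagged frames are untouched.

    Raises
    ------
    UnrecoverableSeriesError
        If every frame is flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(series)
    if mask.shape != (n,):
        raise ValueError("mask length must equal record count")
    if n == 0:
        return CleanedSeries(
            frames=series.frames, x=series.x.copy(), y=series.y.copy(),
            likelihood=series.likelihood.copy(), interpolated_mask=mask.copy(),
            geometry=geometry, fps=series.fps, fly_id=series.fly_id,
            chamber_id=series.chamber_id,
        )
    good = ~mask
    if not good.any():
        raise UnrecoverableSeriesError("all frames flagged; nothing to interpolate from")

    idx = np.arange(n)
    # nearest unflagged index at or before each position (-1 where none)
    prev = np.where(good, idx, -1)
    prev = np.maximum.accumulate(prev)
    # nearest unflagged index at or after each position (n where none)
    nxt = np.where(good, idx, n)
    nxt = np.minimum.accumulate(nxt[::-1])[::-1]

    x = series.x.copy()
    y = series.y.copy()
    bad = np.nonzero(mask)[0]
    p = prev[bad]
    q = nxt[bad]
    # leading run: no preceding anchor -> copy the following one; trailing
    # run symmetric.  Both anchors exist for interior runs.
    p_eff = np.where(p < 0, q, p)
    q_eff = np.where(q >= n, p, q)
    if mode == "midpoint":
        x[bad] = 0.5 * (series.x[p_eff] + series.x[q_eff])
        y[bad] = 0.5 * (series.y[p_eff] + series.y[q_eff])
    elif mode == "linear":
        fi = series.frames[bad].astype(float)
        fp = series.frames[p_eff].astype(float)
        fq = series.frames[q_eff].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(fq > fp, (fi - fp) / (fq - fp), 0.0)
        x[bad] = (1 - w) * series.x[p_eff] + w * series.x[q_eff]
        y[bad] = (1 - w) * series.y[p_eff] + w * series.y[q_eff]
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")

    return CleanedSeries(
        frames=series.frames.copy(), x=x, y=y,
        likelihood=series.likelihood.copy(), interpolated_mask=mask.copy(),
        geometry=geometry, fps=series.fps, fly_id=series.fly_id,
        chamber_id=series.chamber_id,
    )


def clean_series(
    series: TrackingSeries,
    geometry: ChamberGeometry | None = None,
    likelihood_floor: float = DEFAULT_LIKELIHOOD_FLOOR,
    mode: str = "midpoint",
    **infer_kwargs,
) -> tuple[CleanedSeries, dict]:
    """Run the full three-step cleaning and return (cleaned, report).

    A user-supplied ``geometry`` always overrides inference.  The report
    dict records frame counts and the geometry used, for per-file logging.
    """
    if geometry is None:
        geometry = infer_chamber_limits(series, likelihood_floor=likelihood_floor, **infer_kwargs)
    mask = flag_out_of_bounds(series, geometry, likelihood_floor=likelihood_floor)
    cleaned = interpolate_out_of_bounds(series, mask, geometry, mode=mode)
    report = {
        "fly_id": series.fly_id,
        "chamber_id": series.chamber_id,
        "n_frames": len(series),
        "n_flagged": int(mask.sum()),
        "n_interpolated": int(mask.sum()),
        "x_min": geometry.x_min,
        "x_max": geometry.x_max,
        "y_min": geometry.y_min,
        "y_max": geometry.y_max,
    }
    return cleaned, report
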