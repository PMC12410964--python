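"""Reading and writing single-animal pose-tracking tables.

The on-disk dialect is the one the common markerless-tracking networks
emit for a single animal: a comma-separated table with three header rows
(``scorer``, ``bodyparts``, ``coords``), exactly one body part, and the
coordinate triplet ``x, y, likelihood`` per frame.  The first column is a
0-based integer frame index.  Frames per second is experiment
configuration, not part of the file format.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import TrackingFormatError, TrackingParseError, UnsupportedLayoutError

__all__ = ["TrackingSeries", "read_tracking_csv", "write_tracking_csv"]

_HEADER_ROWS = ("scorer", "bodyparts", "coords")
_COORDS = ("x", "y", "likelihood")


@dataclass
class TrackingSeries:
    """Per-frame detections of one fly in one chamber at a fixed frame rate.

    ``x``/``y`` may be NaN for missing detections; ``likelihood`` is the
    tracker's per-frame confidence in [0, 1].  Frame indices are strictly
    increasing but need not be contiguous (dropped frames are permitted).
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 5.0
    fly_id: str = "fly"
    chamber_id: str = "c00"
    scorer: str = "tracker"
    bodypart: str = "fly"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.likelihood) == n):
            raise ValueError("frames, x, y, likelihood must have equal length")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        with np.errstate(invalid="ignore"):
            bad = (self.likelihood < 0) | (self.likelihood > 1)
        if np.any(bad & ~np.isnan(self.likelihood)):
            raise ValueError("likelihood values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in experiment seconds (frame / fps)."""
        return self.frames / self.fps

    @property
    def duration_s(self) -> float:
        """Nominal recording span: (last frame + 1) / fps."""
        if len(self) == 0:
            return 0.0
        return float(self.frames[-1] + 1) / self.fps

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frames, "x": self.x, "y": self.y, "likelihood": self.likelihood}
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackingSeries):
            return NotImplemented
        return (
            np.array_equal(self.frames, other.frames)
            and np.array_equal(self.x, other.x, equal_nan=True)
            and np.array_equal(self.y, other.y, equal_nan=True)
            and np.array_equal(self.likelihood, other.likelihood, equal_nan=True)
            and self.fps == other.fps
        )


def _numeric(col: pd.Series, name: str) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce")
    raw_na = col.isna()
    bad = vals.isna() & ~raw_na
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise TrackingParseError(
            f"non-numeric value {col.iloc[row]!r} in column {name!r} at data row {row}"
        )
    return vals.to_numpy(dtype=float)


def read_tracking_csv(path, fps: float = 5.0, fly_id: str | None = None,
                      chamber_id: str = "c00",
                      likelihood_floor: float = 0.9) -> TrackingSeries:
    """Read a single-animal tracking CSV.

    Low-likelihood rows are *kept* — flagging and interpolation is the
    cleaning stage's job; ``likelihood_floor`` is only stored on the series
    as the downstream default.

    Raises
    ------
    TrackingFormatError
        Malformed three-row header (names the offending row).
    UnsupportedLayoutError
        More than one body part in the table.
    TrackingParseError
        A non-numeric data cell (reports the row number).
    """
    with open(path, "r", encoding="utf-8") as fh:
        head = [fh.readline() for _ in range(3)]
        rest = fh.read()

    labels = [line.split(",", 1)[0].strip() for line in head]
    for expected, got, line in zip(_HEADER_ROWS, labels, head):
        if got != expected:
            raise TrackingFormatError(
                f"expected header row {expected!r}, found {got!r}: {line.strip()!r}"
            )

    scorer_cells = [c.strip() for c in head[0].rstrip("\n").split(",")[1:]]
    bodypart_cells = [c.strip() for c in head[1].rstrip("\n").split(",")[1:]]
    coord_cells = [c.strip() for c in head[2].rstrip("\n").split(",")[1:]]

    bodyparts = list(dict.fromkeys(bodypart_cells))
    if len(bodyparts) != 1:
        raise UnsupportedLayoutError(
            f"expected exactly one bodypart, found {bodyparts}"
        )
    if tuple(coord_cells) != _COORDS:
        raise TrackingFormatError(
            f"expected coords row to be {','.join(_COORDS)}, found {','.join(coord_cells)!r}"
        )

    if rest.strip() == "":
        warnings.warn(f"{path}: tracking table has no data rows", stacklevel=2)
        empty = np.array([], dtype=float)
        return TrackingSeries(
            frames=empty, x=empty, y=empty, likelihood=empty, fps=fps,
            fly_id=fly_id or bodyparts[0], chamber_id=chamber_id,
            scorer=scorer_cells[0] if scorer_cells else "tracker",
            bodypart=bodyparts[0],
        )

    df = pd.read_csv(io.StringIO(rest), header=None,
                     names=["frame", "x", "y", "likelihood"],
                     float_precision="round_trip")
    frames = _numeric(df["frame"], "frame")
    if np.any(frames != np.round(frames)):
        raise TrackingParseError("frame indices must be integers")
    series = TrackingSeries(
        frames=frames.astype(np.int64),
        x=_numeric(df["x"], "x"),
        y=_numeric(df["y"], "y"),
        likelihood=_numeric(df["likelihood"], "likelihood"),
        fps=fps,
        fly_id=fly_id or bodyparts[0],
        chamber_id=chamber_id,
        scorer=scorer_cells[0] if scorer_cells else "tracker",
        bodypart=bodyparts[0],
    )
    series.likelihood_floor = likelihood_floor  # downstream default, not file content
    return series


def write_tracking_csv(series: TrackingSeries, path) -> None:
    """Write a series in the three-row-header dialect.

    Floats are written with :func:`repr` precision, so ``read(write(s))``
    reproduces the series bit-exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        s, b = series.scorer, series.bodypart
        fh.write(f"scorer,{s},{s},{s}\n")
        fh.write(f"bodyparts,{b},{b},{b}\n")
        fh.write("coords,x,y,likelihood\n")
        for f, x, y, lik in zip(series.frames, series.x, series.y, series.likelihood):
            fh.write(f"{int(f)},{float(x)!r},{float(y)!r},{float(lik)!r}\n")
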