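"""Arena and chamber geometry.

Coordinate convention (image convention, matching the tracking ecosystem):
0-based pixel coordinates, origin at the top-left of the camera frame, y
increasing downward.  All rectangles are half-open intervals
``[min, max)`` so that adjacent crop cells never share a pixel.

Two kinds of rectangle live here:

* :class:`CropRect` — one cell of the grid that divides the full camera
  frame into per-chamber crops (integer pixels, row-major order).
* :class:`ChamberGeometry` — the chamber itself in the cropped video's
  coordinates (float pixels), carrying the midline used for virtual
  beam-crossing counts and any labelled food regions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import InvalidLayoutError, OutOfChamberError

__all__ = [
    "ArenaLayout",
    "CropRect",
    "ChamberGeometry",
    "FoodRegion",
    "compute_crop_grid",
    "write_crop_manifest",
]


@dataclass(frozen=True)
class ArenaLayout:
    """Grid layout of chambers within the full camera frame.

    ``margin_*`` are outer margins between the frame edge and the first/last
    cells; ``gap_*`` separate adjacent cells.  All values in integer pixels.
    """

    frame_width: int
    frame_height: int
    rows: int
    cols: int
    margin_x: int = 0
    margin_y: int = 0
    gap_x: int = 0
    gap_y: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise InvalidLayoutError(f"rows and cols must be >= 1, got {self.rows}x{self.cols}")
        if min(self.margin_x, self.margin_y, self.gap_x, self.gap_y) < 0:
            raise InvalidLayoutError("margins and gaps must be non-negative")
        if self.frame_width < 1 or self.frame_height < 1:
            raise InvalidLayoutError("frame dimensions must be positive")

    @property
    def usable_width(self) -> int:
        return self.frame_width - 2 * self.margin_x - (self.cols - 1) * self.gap_x

    @property
    def usable_height(self) -> int:
        return self.frame_height - 2 * self.margin_y - (self.rows - 1) * self.gap_y


@dataclass(frozen=True)
class CropRect:
    """One grid cell: origin (top-left, inclusive) plus size, with its grid indices."""

    x0: int
    y0: int
    width: int
    height: int
    row: int
    col: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidLayoutError("crop rectangle must have positive size")
        if self.x0 < 0 or self.y0 < 0:
            raise InvalidLayoutError("crop rectangle origin must be non-negative")


def _partition(total: int, parts: int) -> list[int]:
    """Split ``total`` pixels into ``parts`` integer widths differing by at most 1.

    Remainder pixels go to the lowest-index parts, deterministically.
    """
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def compute_crop_grid(layout: ArenaLayout) -> list[CropRect]:
    """Divide the camera frame into a rows x cols grid of crop rectangles.

    Returns cells in row-major order.  Within a row (column), cell widths
    (heights) differ by at most one pixel; the union of cells plus margins
    and gaps tiles the frame exactly.

    Raises
    ------
    InvalidLayoutError
        If margins/gaps leave no usable area, or fewer than one pixel per
        cell in either axis.
    """
    uw, uh = layout.usable_width, layout.usable_height
    if uw <= 0 or uh <= 0:
        raise InvalidLayoutError(
            f"usable area is {uw}x{uh} px after margins and gaps; layout is infeasible"
        )
    if uw < layout.cols or uh < layout.rows:
        raise InvalidLayoutError("usable area smaller than one pixel per grid cell")

    widths = _partition(uw, layout.cols)
    heights = _partition(uh, layout.rows)

    rects: list[CropRect] = []
    y = layout.margin_y
    for r, h in enumerate(heights):
        x = layout.margin_x
        for c, w in enumerate(widths):
            rects.append(CropRect(x0=x, y0=y, width=w, height=h, row=r, col=c))
            x += w + layout.gap_x
        y += h + layout.gap_y
    return rects


def write_crop_manifest(rects: Sequence[CropRect], path) -> None:
    """Export a crop manifest CSV consumable by external video-cropping tools.

    Columns: ``chamber_id,row,col,x0,y0,width,height``; chamber ids are
    ``c00, c01, ...`` in row-major order.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chamber_id", "row", "col", "x0", "y0", "width", "height"])
        for i, r in enumerate(rects):
            writer.writerow([f"c{i:02d}", r.row, r.col, r.x0, r.y0, r.width, r.height])


@dataclass(frozen=True)
class FoodRegion:
    """A labelled interval along the chamber's long axis (pixels, half-open)."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InvalidLayoutError(f"food region {self.label!r} has empty extent")

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber rectangle with midline, food regions and optional mm scale.

    The long axis is the axis along which the fly's position is summarised
    for beam-crossing and preference analyses.  If not given it is inferred
    as the longer of the two dimensions.  The midline defaults to the centre
    of the long axis — the position of the virtual infrared beam.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    long_axis: Literal["horizontal", "vertical"] | None = None
    midline: float | None = None
    food_regions: tuple[FoodRegion, ...] = field(default_factory=tuple)
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidLayoutError("chamber must have positive extent in both axes")
        if self.long_axis is None:
            axis = "horizontal" if (self.x_max - self.x_min) >= (self.y_max - self.y_min) else "vertical"
            object.__setattr__(self, "long_axis", axis)
        lo, hi = self.long_interval
        if self.midline is None:
            object.__setattr__(self, "midline", 0.5 * (lo + hi))
        if not (lo < self.midline < hi):
            raise InvalidLayoutError("midline must lie strictly inside the chamber's long axis")
        regions = sorted(self.food_regions, key=lambda r: r.start)
        for r in regions:
            if r.start < lo - 1e-9 or r.end > hi + 1e-9:
                raise InvalidLayoutError(f"food region {r.label!r} extends outside the chamber")
        for a, b in zip(regions, regions[1:]):
            if b.start < a.end:
                raise InvalidLayoutError(f"food regions {a.label!r} and {b.label!r} overlap")

    # -- basic accessors ---------------------------------------------------

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def long_interval(self) -> tuple[float, float]:
        """(lo, hi) of the long axis, in pixels."""
        if self.long_axis == "horizontal":
            return (self.x_min, self.x_max)
        return (self.y_min, self.y_max)

    def long_coord(self, x, y):
        """Project a point (or arrays) onto the long axis."""
        return x if self.long_axis == "horizontal" else y

    # -- predicates --------------------------------------------------------

    def contains(self, x: float, y: float) -> bool:
        """True iff the point lies inside the half-open chamber rectangle."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def midline_side(self, x: float, y: float, prev: int | None = None) -> int:
        """Which side of the virtual beam a point is on: -1 (low) or +1 (high).

        A point exactly on the midline keeps the previously held side when
        ``prev`` is given (hysteresis: grazing the beam is not a crossing);
        standalone queries return -1.

        Raises
        ------
        OutOfChamberError
            If the point is outside the chamber.
        """
        if not self.contains(x, y):
            raise OutOfChamberError(f"point ({x}, {y}) lies outside the chamber")
        c = self.long_coord(x, y)
        if c < self.midline:
            return -1
        if c > self.midline:
            return +1
        return prev if prev is not None else -1
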