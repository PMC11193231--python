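"""Spatial context: obstacle rows and left/right track side.

Obstacle stations repeat along the walking path, each marked by a pair of
tennis balls on supports flanking a hurdle.  In the egocentric view the
stations project to horizontal bands, so the vertical (y) pixel coordinate
of the detected tennis balls is enough to cluster them into rows; every
other object is then assigned the row whose representative line is
vertically closest.  Row 1 is the nearest row: closer floor objects project
lower in the frame, i.e. to a *larger* image y.

Left/right side is decided against a separator line fitted through the gap
between the two parallel track lanes in the binary segmentation mask: on
each mask scanline showing exactly two foreground runs, the midpoint of the
gap is recorded, and a least-squares line ``x = a*y + b`` is fitted through
those midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .geometry import Detection
from .io import MaskImage

__all__ = [
    "Row",
    "RowModel",
    "SeparatorLine",
    "SideLabel",
    "DEFAULT_ROW_GAP_PX",
    "cluster_balls_into_rows",
    "assign_object_row",
    "fit_track_separator",
    "classify_side",
]

#: Vertical pixel gap at or above which consecutive balls start a new row.
DEFAULT_ROW_GAP_PX = 50.0

#: Minimum fraction of foreground scanlines that must show exactly two track
#: runs for the separator to be considered identifiable.
_MIN_TWO_RUN_FRACTION = 0.30


class SideLabel(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Row:
    """One obstacle row: member ball detections and their mean y-midpoint."""

    members: tuple[Detection, ...]
    row_line_y: float
    row_index: int


@dataclass(frozen=True)
class RowModel:
    """Rows ordered by ascending image y; ``row_index`` 1 = nearest (largest y)."""

    rows: tuple[Row, ...]
    gap_threshold: float = DEFAULT_ROW_GAP_PX

    def __len__(self) -> int:
        return len(self.rows)

    def by_index(self, row_index: int) -> Row:
        for row in self.rows:
            if row.row_index == row_index:
                return row
        raise KeyError(f"no row with index {row_index}")


@dataclass(frozen=True)
class SeparatorLine:
    """Inter-track separator ``x = a*y + b``, valid over ``[y_min, y_max]``."""

    a: float
    b: float
    y_min: float
    y_max: float

    def x_at(self, y: float) -> float:
        """Separator x at image row y; y outside the fitted range is clamped."""
        y = min(max(y, self.y_min), self.y_max)
        return self.a * y + self.b


def cluster_balls_into_rows(
    balls: Sequence[Detection], gap_threshold: float = DEFAULT_ROW_GAP_PX
) -> RowModel:
    """Cluster tennis-ball detections into obstacle rows by image y.

    Balls are sorted by box y-midpoint; a gap >= ``gap_threshold`` pixels
    between consecutive midpoints starts a new row.  A gap strictly below the
    threshold keeps the balls in the same row.  The result partitions the
    input exactly and is invariant to input order.
    """
    for b in balls:
        if b.class_label != "tennis_ball":
            raise ValueError(f"expected tennis_ball detections, got {b.class_label!r}")
    if gap_threshold <= 0:
        raise ValueError(f"gap_threshold must be positive, got {gap_threshold}")
    if not balls:
        return RowModel(rows=(), gap_threshold=gap_threshold)

    ordered = sorted(balls, key=lambda d: d.box.center.y)
    groups: list[list[Detection]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.box.center.y - prev.box.center.y >= gap_threshold:
            groups.append([cur])
        else:
            groups[-1].append(cur)

    n = len(groups)
    rows = tuple(
        Row(
            members=tuple(g),
            row_line_y=float(np.mean([d.box.center.y for d in g])),
            row_index=n - i,  # ascending y -> descending index; last (lowest) row is 1
        )
        for i, g in enumerate(groups)
    )
    return RowModel(rows=rows, gap_threshold=gap_threshold)


def assign_object_row(obj: Detection, rm: RowModel) -> int:
    """Row index whose row line is vertically closest to the object midpoint.

    Exact equidistance goes to the row with the larger ``row_line_y`` (the
    nearer row) — the conservative choice when deciding whether the wearer is
    attending the immediate obstacle.
    """
    if not rm.rows:
        raise ValueError("no rows: cannot assign an object row")
    y = obj.box.center.y
    best = min(rm.rows, key=lambda r: (abs(y - r.row_line_y), -r.row_line_y))
    return best.row_index


def _foreground_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) column index pairs of each foreground run; stop exclusive."""
    padded = np.diff(np.concatenate(([0], row.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def fit_track_separator(mask: MaskImage) -> SeparatorLine:
    """Fit the separator line through the gap between the two track lanes.

    Every scanline with exactly two foreground runs contributes the midpoint
    of the gap between them; a least-squares line ``x = a*y + b`` is fitted
    through the midpoints.  Raises ValueError("separator not identifiable")
    when fewer than 30% of foreground scanlines (or fewer than 2 in total)
    qualify — e.g. when only one track lane is visible.
    """
    px = mask.pixels
    fg_rows = np.flatnonzero(px.any(axis=1))
    ys: list[float] = []
    mids: list[float] = []
    for y in fg_rows.tolist():
        runs = _foreground_runs(px[y])
        if len(runs) == 2:
            (_, left_stop), (right_start, _) = runs
            # left_stop is exclusive: last fg column of the left run is left_stop-1
            mids.append(((left_stop - 1) + right_start) / 2.0)
            ys.append(float(y))
    if len(fg_rows) == 0 or len(ys) < max(2, _MIN_TWO_RUN_FRACTION * len(fg_rows)):
        raise ValueError(
            "separator not identifiable: "
            f"{len(ys)} two-run scanlines out of {len(fg_rows)} foreground scanlines"
        )
    y_arr = np.asarray(ys)
    m_arr = np.asarray(mids)
    if np.ptp(y_arr) == 0:  # single qualifying scanline y cannot happen (>=2 distinct?)
        a, b = 0.0, float(m_arr.mean())
    else:
        a, b = np.polyfit(y_arr, m_arr, deg=1)
    return SeparatorLine(a=float(a), b=float(b), y_min=float(y_arr.min()), y_max=float(y_arr.max()))


def classify_side(obj: Detection, sep: SeparatorLine) -> SideLabel:
    """Left if the object's x-midpoint is left of the separator, else right.

    The object's y-midpoint is clamped into the separator's fitted y-range;
    a midpoint exactly on the line counts as right (the active lane).
    """
    c = obj.box.center
    return SideLabel.LEFT if c.x < sep.x_at(c.y) else SideLabel.RIGHT
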