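"""Resolve what the wearer's gaze point overlaps.

The eye-tracking glasses report a per-frame gaze point in scene-camera pixel
coordinates (and superimpose a crosshair glyph on the video).  This module
hit-tests that point against detected object boxes and against the binary
walking-track mask, and can recover a gaze point from a detected crosshair
when no external gaze stream is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .geometry import CROSSHAIR_LABEL, CornerBox, Detection, PixelPoint, point_in_box

__all__ = [
    "GazeSample",
    "GazeHit",
    "find_gaze_overlaps",
    "resolve_primary_target",
    "gaze_on_track",
    "gaze_from_crosshair",
]


@dataclass(frozen=True)
class GazeSample:
    """A per-frame gaze point; ``valid`` is False for blank or out-of-frame gaze."""

    frame_index: int
    point: PixelPoint
    valid: bool = True

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be non-negative, got {self.frame_index}")


@dataclass(frozen=True)
class GazeHit:
    """A detection whose bounding box contains the gaze point."""

    detection: Detection
    box_area: float


def find_gaze_overlaps(g: GazeSample, dets: Sequence[Detection]) -> list[GazeHit]:
    """All detections whose box contains the gaze point, ascending by box area.

    Ties in area keep input order (stable sort).  Raises on an invalid gaze
    sample: callers must filter invalid samples themselves.
    """
    if not g.valid:
        raise ValueError("cannot hit-test an invalid gaze sample")
    hits = [GazeHit(d, d.box.area) for d in dets if point_in_box(g.point, d.box)]
    hits.sort(key=lambda h: h.box_area)
    return hits


# Priority used to break exact area ties between overlapping candidates:
# the obstacle itself outranks the opening markers.
_CORE_PRIORITY = {"hurdle": 0, "tennis_ball": 1, "support": 2}


def resolve_primary_target(hits: Sequence[GazeHit]) -> Optional[Detection]:
    """Pick the single detection the gaze is most specifically on.

    The smallest-area hit wins (a nested box is a more specific target than
    the box enclosing it).  Exact area ties are broken by core-object
    priority (hurdle > tennis_ball > support > anything else), then by
    input order.
    """
    if not hits:
        return None
    best = min(
        enumerate(hits),
        key=lambda ih: (
            ih[1].box_area,
            _CORE_PRIORITY.get(ih[1].detection.class_label, len(_CORE_PRIORITY)),
            ih[0],
        ),
    )
    return best[1].detection


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def gaze_on_track(g: GazeSample, mask) -> bool:
    """True iff the track mask is foreground at the gaze pixel.

    The sub-pixel gaze point is rounded half-away-from-zero to the nearest
    pixel; a rounded coordinate landing one past the last row/column (a gaze
    exactly on the frame edge) is clamped back inside.
    """
    if not g.valid:
        raise ValueError("cannot test track overlap for an invalid gaze sample")
    h, w = mask.pixels.shape
    col = min(max(_round_half_away(g.point.x), 0), w - 1)
    row = min(max(_round_half_away(g.point.y), 0), h - 1)
    return bool(mask.pixels[row, col])


def gaze_from_crosshair(
    dets: Sequence[Detection], frame_index: int = 0
) -> Optional[GazeSample]:
    """Recover the gaze point from a detected eye-tracker crosshair glyph.

    Returns the centre of the highest-confidence crosshair detection as a
    valid gaze sample, or None when no crosshair class is present.  Intended
    as a fallback when no external gaze stream accompanies the video.
    """
    crosshairs = [d for d in dets if d.class_label == CROSSHAIR_LABEL]
    if not crosshairs:
        return None
    best = max(enumerate(crosshairs), key=lambda id_: (id_[1].confidence, -id_[0]))
    box: CornerBox = best[1].box
    return GazeSample(frame_index=frame_index, point=box.center, valid=True)
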