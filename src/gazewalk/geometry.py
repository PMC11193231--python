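"""Pixel-space geometric primitives shared by every other module.

Conventions
-----------
* The image origin is the top-left corner; ``x`` grows rightward and
  ``y`` grows downward, both in pixel units.
* Boxes are real-valued *closed* intervals ``[x1, x2] x [y1, y2]``; a point
  on a box edge is inside the box.  This is deliberately conservative for
  attention detection: a gaze pixel sitting exactly on an object boundary
  counts as a hit.
* Normalized (detector-style) boxes store fractions of the frame size in
  ``[0, 1]`` as ``class_id x_mid y_mid width height``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FrameSize",
    "PixelPoint",
    "CornerBox",
    "YoloBox",
    "Detection",
    "ClassTaxonomy",
    "FULL_HD",
    "CROSSHAIR_LABEL",
    "yolo_to_corner",
    "corner_to_yolo",
    "point_in_box",
    "box_iou",
    "non_max_suppression",
]

#: Class label used for the eye-tracker crosshair superimposed on the video.
CROSSHAIR_LABEL = "eye_tracker_crosshair"


@dataclass(frozen=True)
class FrameSize:
    """Frame dimensions in pixels."""

    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError(f"frame size must be >= 1x1, got {self.width}x{self.height}")


#: Default frame size of the scene camera (full HD).
FULL_HD = FrameSize(1920, 1080)


@dataclass(frozen=True)
class PixelPoint:
    """A point in pixel coordinates (origin top-left, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point coordinates must be finite, got ({self.x}, {self.y})")


@dataclass(frozen=True)
class CornerBox:
    """Axis-aligned box in corner format ``(x1, y1, x2, y2)``, pixels."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v):
                raise ValueError("box coordinates must be finite")
        if self.x1 > self.x2 or self.y1 > self.y2:
            raise ValueError(
                f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2}) "
                "requires x1 <= x2 and y1 <= y2"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> PixelPoint:
        return PixelPoint((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)


@dataclass(frozen=True)
class YoloBox:
    """Normalized detector box: class id plus midpoint/size fractions in [0, 1]."""

    class_id: int
    x_mid: float
    y_mid: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be non-negative, got {self.class_id}")
        for name in ("x_mid", "y_mid", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class Detection:
    """One classified, localized object in a frame."""

    box: CornerBox
    class_label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


# Labels that are directly task-relevant for obstacle crossing: the hurdle to
# be crossed and the tennis balls / supports that mark the horizontal opening.
_CORE_LABELS = ("tennis_ball", "support", "hurdle")

_DEFAULT_LABELS = (
    "hurdle",
    "tennis_ball",
    "support",
    "animate_distractor",
    "bucket",
    "computer",
    CROSSHAIR_LABEL,
    # Remaining lab clutter classes; names are configurable, the pipeline
    # only distinguishes core vs non-core.
    "chair",
    "desk",
    "door",
    "tripod",
    "cable_run",
    "marker_cone",
    "poster",
    "whiteboard",
    "monitor",
    "bag",
    "bin",
)


@dataclass(frozen=True)
class ClassTaxonomy:
    """Ordered class-label list; index in ``labels`` is the annotation class id.

    ``core_labels`` marks the task-relevant classes (tennis ball, support,
    hurdle by default); everything else is treated as a potential distractor.
    """

    labels: tuple[str, ...]
    core_labels: frozenset[str] = field(default=frozenset(_CORE_LABELS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate class labels in taxonomy")
        unknown = self.core_labels - set(self.labels)
        if unknown:
            raise ValueError(f"core labels not in taxonomy: {sorted(unknown)}")

    @classmethod
    def default(cls) -> "ClassTaxonomy":
        """The 18-class lab taxonomy used throughout this package."""
        return cls(labels=_DEFAULT_LABELS)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in taxonomy") from None

    def label(self, class_id: int) -> str:
        if not 0 <= class_id < len(self.labels):
            raise KeyError(
                f"class id {class_id} outside taxonomy of {len(self.labels)} classes"
            )
        return self.labels[class_id]

    def is_core(self, label: str) -> bool:
        return label in self.core_labels


def yolo_to_corner(b: YoloBox, fs: FrameSize) -> CornerBox:
    """Convert a normalized midpoint/size box to pixel corner format."""
    x1 = (b.x_mid - b.w / 2.0) * fs.width
    x2 = (b.x_mid + b.w / 2.0) * fs.width
    y1 = (b.y_mid - b.h / 2.0) * fs.height
    y2 = (b.y_mid + b.h / 2.0) * fs.height
    return CornerBox(x1, y1, x2, y2)


def corner_to_yolo(b: CornerBox, fs: FrameSize, class_id: int = 0) -> YoloBox:
    """Convert a pixel corner box to normalized midpoint/size format.

    The box must lie inside the frame; clamping out-of-frame boxes is the
    caller's responsibility.
    """
    if b.x1 < 0 or b.y1 < 0 or b.x2 > fs.width or b.y2 > fs.height:
        raise ValueError(
            f"box ({b.x1}, {b.y1}, {b.x2}, {b.y2}) extends outside "
            f"frame {fs.width}x{fs.height}"
        )
    return YoloBox(
        class_id=class_id,
        x_mid=(b.x1 + b.x2) / (2.0 * fs.width),
        y_mid=(b.y1 + b.y2) / (2.0 * fs.height),
        w=(b.x2 - b.x1) / fs.width,
        h=(b.y2 - b.y1) / fs.height,
    )


def point_in_box(p: PixelPoint, b: CornerBox) -> bool:
    """Closed-interval containment test (boundary points are inside)."""
    return b.x1 <= p.x <= b.x2 and b.y1 <= p.y <= b.y2


def box_iou(a: CornerBox, b: CornerBox) -> float:
    """Intersection over union of two corner boxes.

    Returns 0 for disjoint boxes and, by convention, 0 when the union has
    zero area (two zero-area boxes), avoiding a 0/0.
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def _nms_sort_key(indexed: tuple[int, Detection]) -> tuple[float, float, int]:
    i, d = indexed
    # Descending confidence, then larger area, then input order.
    return (-d.confidence, -d.box.area, i)


def non_max_suppression(
    dets: Sequence[Detection] | Iterable[Detection], iou_threshold: float
) -> list[Detection]:
    """Greedy class-wise non-maximum suppression.

    Detections are visited in descending confidence (ties: larger area, then
    input order); each kept detection suppresses later same-class detections
    overlapping it with IoU strictly above ``iou_threshold``.  Suppression
    never crosses class boundaries.  The survivors are returned in the visit
    order (descending confidence).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    ordered = sorted(enumerate(dets), key=_nms_sort_key)
    kept: list[Detection] = []
    for _, cand in ordered:
        suppressed = any(
            k.class_label == cand.class_label and box_iou(k.box, cand.box) > iou_threshold
            for k in kept
        )
        if not suppressed:
            kept.append(cand)
    return kept
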