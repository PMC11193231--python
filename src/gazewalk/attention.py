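"""Per-frame attention classification and the contextual CSV output.

The walking protocol always navigates the *right* lane from the wearer's
perspective, so gaze on the right lane is task-relevant while gaze on the
left (opposite) lane is a distraction.  Fusing the gaze target, its obstacle
row, its track side, and track-surface overlap yields one categorical
attention state per frame:

* ``ATTEND_IMMEDIATE_OBSTACLE`` — gaze on a core object (hurdle / tennis
  ball / support) in the nearest row on the active side: planning the
  imminent crossing.
* ``ATTEND_PLANNING`` — gaze on a core object further ahead on the active
  side: look-ahead planning.
* ``TRACK_SURFACE`` — gaze on the walking surface of the active lane:
  thinking about foot placement.
* ``DISTRACTED_LEFT_TRACK`` — gaze on the opposite lane or its obstacles.
* ``DISTRACTED_OBJECT`` — gaze on a non-core object (lab clutter, people).
* ``UNCLASSIFIED`` — valid gaze on nothing recognizable.
* ``INVALID_GAZE`` — no usable gaze estimate this frame.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .gaze import (
    GazeSample,
    find_gaze_overlaps,
    gaze_from_crosshair,
    gaze_on_track,
    resolve_primary_target,
)
from .geometry import CROSSHAIR_LABEL, ClassTaxonomy, Detection, PixelPoint
from .io import MaskImage
from .spatial import (
    DEFAULT_ROW_GAP_PX,
    SeparatorLine,
    SideLabel,
    assign_object_row,
    classify_side,
    cluster_balls_into_rows,
    fit_track_separator,
)

__all__ = [
    "AttentionState",
    "AttentionRecord",
    "SequenceSummary",
    "DwellEvent",
    "classify_attention",
    "contextualize_frame",
    "contextualize_sequence",
    "write_context_csv",
    "read_context_csv",
]

DEFAULT_FPS = 24.0


class AttentionState(str, Enum):
    ATTEND_IMMEDIATE_OBSTACLE = "ATTEND_IMMEDIATE_OBSTACLE"
    ATTEND_PLANNING = "ATTEND_PLANNING"
    TRACK_SURFACE = "TRACK_SURFACE"
    DISTRACTED_LEFT_TRACK = "DISTRACTED_LEFT_TRACK"
    DISTRACTED_OBJECT = "DISTRACTED_OBJECT"
    UNCLASSIFIED = "UNCLASSIFIED"
    INVALID_GAZE = "INVALID_GAZE"


@dataclass(frozen=True)
class AttentionRecord:
    """The per-frame contextual verdict."""

    frame_index: int
    gaze_x: Optional[float]
    gaze_y: Optional[float]
    target_class: Optional[str]
    target_row: Optional[int]
    target_side: Optional[SideLabel]
    on_track: bool
    state: AttentionState


def classify_attention(
    target: Optional[Detection],
    row: Optional[int],
    side: Optional[SideLabel],
    on_track: bool,
    gaze_valid: bool,
    taxonomy: ClassTaxonomy,
) -> AttentionState:
    """Total decision cascade from fused context to one attention state.

    First match wins.  ``side`` carries the object's side when a target
    exists and the gaze point's side otherwise; a missing side (no usable
    track mask) is treated as right — the pipeline never accuses the wearer
    of a left-lane distraction without mask evidence.  A core target whose
    row cannot be established (no ball rows in view) degrades to
    ``ATTEND_PLANNING``: the object is task-relevant but its immediacy is
    unknown.
    """
    if not gaze_valid:
        return AttentionState.INVALID_GAZE
    effective_side = side if side is not None else SideLabel.RIGHT
    if target is not None:
        if taxonomy.is_core(target.class_label):
            if effective_side is SideLabel.LEFT:
                return AttentionState.DISTRACTED_LEFT_TRACK
            if row == 1:
                return AttentionState.ATTEND_IMMEDIATE_OBSTACLE
            return AttentionState.ATTEND_PLANNING
        return AttentionState.DISTRACTED_OBJECT
    if on_track:
        if effective_side is SideLabel.LEFT:
            return AttentionState.DISTRACTED_LEFT_TRACK
        return AttentionState.TRACK_SURFACE
    return AttentionState.UNCLASSIFIED


def contextualize_frame(
    dets: Sequence[Detection],
    gaze: Optional[GazeSample],
    mask: Optional[MaskImage],
    taxonomy: ClassTaxonomy,
    gap_threshold: float = DEFAULT_ROW_GAP_PX,
    frame_index: Optional[int] = None,
    separator: Optional[SeparatorLine] = None,
) -> AttentionRecord:
    """Resolve one frame's detections + gaze (+ mask) into an AttentionRecord.

    When ``gaze`` is None the gaze point is recovered from a detected
    crosshair, if any; an externally supplied gaze stream always takes
    precedence.  Crosshair detections mark the gaze point itself and are
    never eligible as gaze targets.  ``separator`` short-circuits the
    per-frame separator fit when the caller has already fitted one.
    """
    if gaze is None:
        gaze = gaze_from_crosshair(dets, frame_index=frame_index or 0)
    fi = frame_index if frame_index is not None else (gaze.frame_index if gaze else 0)

    if gaze is None or not gaze.valid:
        return AttentionRecord(
            frame_index=fi,
            gaze_x=None,
            gaze_y=None,
            target_class=None,
            target_row=None,
            target_side=None,
            on_track=False,
            state=AttentionState.INVALID_GAZE,
        )

    candidates = [d for d in dets if d.class_label != CROSSHAIR_LABEL]
    target = resolve_primary_target(find_gaze_overlaps(gaze, candidates))

    row: Optional[int] = None
    if target is not None:
        balls = [d for d in candidates if d.class_label == "tennis_ball"]
        rm = cluster_balls_into_rows(balls, gap_threshold=gap_threshold)
        if len(rm):
            row = assign_object_row(target, rm)

    sep = separator
    if sep is None and mask is not None:
        try:
            sep = fit_track_separator(mask)
        except ValueError:
            sep = None  # one lane visible, or no track: side stays unknown

    side: Optional[SideLabel] = None
    if sep is not None:
        probe = target if target is not None else Detection(
            box=_point_box(gaze.point), class_label=CROSSHAIR_LABEL, confidence=1.0
        )
        side = classify_side(probe, sep)

    on_track = gaze_on_track(gaze, mask) if mask is not None else False
    state = classify_attention(
        target=target,
        row=row,
        side=side,
        on_track=on_track,
        gaze_valid=True,
        taxonomy=taxonomy,
    )
    return AttentionRecord(
        frame_index=fi,
        gaze_x=gaze.point.x,
        gaze_y=gaze.point.y,
        target_class=target.class_label if target is not None else None,
        target_row=row if target is not None else None,
        target_side=side if target is not None else None,
        on_track=on_track,
        state=state,
    )


def _point_box(p: PixelPoint):
    from .geometry import CornerBox

    return CornerBox(p.x, p.y, p.x, p.y)


@dataclass(frozen=True)
class DwellEvent:
    """A maximal run of consecutive frames on the same gaze target."""

    target_class: str
    start_frame: int
    n_frames: int
    seconds: float


@dataclass
class SequenceSummary:
    n_frames: int
    state_counts: Counter
    target_counts: Counter
    dwell_events: list[DwellEvent]


def contextualize_sequence(
    frames: Iterable[tuple[Sequence[Detection], Optional[GazeSample], Optional[MaskImage]]],
    taxonomy: ClassTaxonomy,
    fps: float = DEFAULT_FPS,
    gap_threshold: float = DEFAULT_ROW_GAP_PX,
) -> tuple[list[AttentionRecord], SequenceSummary]:
    """Contextualize an ordered iterable of (detections, gaze, mask) frames.

    Returns one record per frame plus a summary with per-state and per-target
    counts and dwell events (consecutive same-target run length x frame
    period at ``fps``).
    """
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    records: list[AttentionRecord] = []
    for i, (dets, gz, mask) in enumerate(frames):
        fi = gz.frame_index if gz is not None else i
        records.append(
            contextualize_frame(
                dets, gz, mask, taxonomy, gap_threshold=gap_threshold, frame_index=fi
            )
        )

    state_counts: Counter = Counter(r.state for r in records)
    target_counts: Counter = Counter(
        r.target_class for r in records if r.target_class is not None
    )

    dwell_events: list[DwellEvent] = []
    run_class: Optional[str] = None
    run_start = 0
    run_len = 0
    for r in records:
        if r.target_class is not None and r.target_class == run_class:
            run_len += 1
        else:
            if run_class is not None:
                dwell_events.append(
                    DwellEvent(run_class, run_start, run_len, run_len / fps)
                )
            run_class = r.target_class
            run_start = r.frame_index
            run_len = 1 if r.target_class is not None else 0
    if run_class is not None:
        dwell_events.append(DwellEvent(run_class, run_start, run_len, run_len / fps))

    summary = SequenceSummary(
        n_frames=len(records),
        state_counts=state_counts,
        target_counts=target_counts,
        dwell_events=dwell_events,
    )
    return records, summary


_CSV_HEADER = [
    "frame_index",
    "gaze_x",
    "gaze_y",
    "target_class",
    "target_row",
    "target_side",
    "on_track",
    "state",
]


def write_context_csv(records: Sequence[AttentionRecord], path: str | Path) -> None:
    """Write the contextual output CSV (empty strings for absent fields)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.frame_index,
                    "" if r.gaze_x is None else f"{r.gaze_x:.3f}",
                    "" if r.gaze_y is None else f"{r.gaze_y:.3f}",
                    r.target_class or "",
                    "" if r.target_row is None else r.target_row,
                    r.target_side.value if r.target_side is not None else "",
                    "true" if r.on_track else "false",
                    r.state.value,
                ]
            )


def read_context_csv(path: str | Path) -> list[AttentionRecord]:
    """Read back a contextual output CSV written by :func:`write_context_csv`."""
    records: list[AttentionRecord] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                AttentionRecord(
                    frame_index=int(row["frame_index"]),
                    gaze_x=float(row["gaze_x"]) if row["gaze_x"] else None,
                    gaze_y=float(row["gaze_y"]) if row["gaze_y"] else None,
                    target_class=row["target_class"] or None,
                    target_row=int(row["target_row"]) if row["target_row"] else None,
                    target_side=SideLabel(row["target_side"]) if row["target_side"] else None,
                    on_track=row["on_track"] == "true",
                    state=AttentionState(row["state"]),
                )
            )
    return records
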