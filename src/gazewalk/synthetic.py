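"""Seeded synthetic generator of the obstacle-crossing lab scene.

Stands in for real eye-tracker video: it builds a metric model of the lab —
a two-sided 12 m x 0.92 m black walking loop with three hurdle stations per
side every 3 m, each hurdle flanked by tennis balls on supports, plus
off-track distractor objects — walks a head-mounted pinhole camera along the
active (right) lane, and emits, per frame, a flat-shaded raster, ground-truth
normalized annotations, a binary track mask, a scheduled gaze sample, and the
ground-truth attention record derived from the metric scene graph (never from
the pipeline under test).

World coordinates are metres: x lateral (positive to the wearer's right),
y along the walk, z up.  The right lane is centred on x = 0; the left
(opposite) lane lies across a configurable gap.  Hurdle heights are drawn
from the protocol's levels {5, 7.5, 10, 12.5}% of body height, with at least
one 10% hurdle per side.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
from skimage.draw import polygon as _draw_polygon

from .attention import AttentionRecord, AttentionState
from .gaze import GazeSample
from .geometry import (
    CROSSHAIR_LABEL,
    ClassTaxonomy,
    CornerBox,
    Detection,
    FrameSize,
    FULL_HD,
    PixelPoint,
)
from .io import FrameAnnotation, MaskImage, write_gaze_csv, write_mask, write_yolo_annotation
from .spatial import SideLabel

__all__ = [
    "LabLayout",
    "SceneEntity",
    "CameraModel",
    "CameraPose",
    "GazeSchedule",
    "FixationSegment",
    "EntityFixation",
    "TrackFixation",
    "WorldPointFixation",
    "BlankFixation",
    "SyntheticFrame",
    "build_default_layout",
    "simulate_walk",
    "render_frame",
    "simulate_gaze",
    "default_gaze_schedule",
    "generate_dataset",
    "nearest_row_gap_px",
]

#: Protocol hurdle heights as fractions of body height.
HURDLE_HEIGHT_LEVELS = (0.05, 0.075, 0.10, 0.125)

#: Eye height as a fraction of body height (standard anthropometry).
EYE_HEIGHT_RATIO = 0.936

_NEAR_PLANE = 0.05  # metres; points closer than this are culled
_TENNIS_BALL_RADIUS = 0.033


@dataclass(frozen=True)
class SceneEntity:
    """One physical object in the lab, as an axis-aligned metric box."""

    entity_id: int
    class_label: str
    center: tuple[float, float, float]  # metres
    size: tuple[float, float, float]  # metres
    lane: Optional[str] = None  # "right" | "left" | None (off-track)
    station: Optional[float] = None  # along-walk position of its obstacle row


@dataclass(frozen=True)
class LabLayout:
    """Metric description of the lab, including the placed entities."""

    track_length: float = 12.0
    track_width: float = 0.92
    hurdle_spacing: float = 3.0
    hurdles_per_side: int = 3
    hurdle_height_levels: tuple[float, ...] = HURDLE_HEIGHT_LEVELS
    body_height: float = 1.66
    lane_gap: float = 1.0
    support_height: float = 0.15
    entities: tuple[SceneEntity, ...] = ()

    def __post_init__(self) -> None:
        if self.hurdles_per_side * self.hurdle_spacing > self.track_length:
            raise ValueError(
                f"{self.hurdles_per_side} stations x {self.hurdle_spacing} m spacing "
                f"exceed the {self.track_length} m track"
            )

    @property
    def stations(self) -> tuple[float, ...]:
        """Along-walk positions of the obstacle rows (same on both sides)."""
        return tuple(
            self.hurdle_spacing * (i + 1) for i in range(self.hurdles_per_side)
        )

    @property
    def right_lane_center_x(self) -> float:
        return 0.0

    @property
    def left_lane_center_x(self) -> float:
        return -(self.track_width + self.lane_gap)

    @property
    def gap_center_x(self) -> float:
        """Metric x of the mid-line between the two lanes."""
        return -(self.track_width / 2.0 + self.lane_gap / 2.0)

    def lane_center_x(self, lane: str) -> float:
        return self.right_lane_center_x if lane == "right" else self.left_lane_center_x

    def find_entity(
        self,
        class_label: str,
        lane: Optional[str] = None,
        station: Optional[float] = None,
    ) -> SceneEntity:
        for e in self.entities:
            if e.class_label != class_label:
                continue
            if lane is not None and e.lane != lane:
                continue
            if station is not None and (e.station is None or abs(e.station - station) > 1e-9):
                continue
            return e
        raise KeyError(f"no entity ({class_label}, lane={lane}, station={station})")

    def entity(self, entity_id: int) -> SceneEntity:
        for e in self.entities:
            if e.entity_id == entity_id:
                return e
        raise KeyError(f"no entity with id {entity_id}")


_DEFAULT_DISTRACTORS = (
    # (class_label, x, y, size) — off-track lab clutter
    ("animate_distractor", 1.55, 4.5, (0.5, 0.4, 1.7)),
    ("bucket", 1.25, 7.5, (0.3, 0.3, 0.35)),
    ("computer", -3.35, 5.5, (0.45, 0.35, 0.4)),
)


def build_default_layout(
    body_height: float = 1.66,
    seed: int = 0,
    *,
    lane_gap: float = 1.0,
    support_height: float = 0.15,
) -> LabLayout:
    """Build the default lab: 6 hurdles (3 per side, 3 m apart) plus markers.

    Each hurdle station carries a hurdle spanning the lane and a tennis ball
    on a support at each lane edge.  Heights are drawn per station from the
    protocol levels under ``seed``, with one station per side forced to the
    10% level.  Distractors are placed off-track with small seeded jitter.
    """
    if not 1.4 <= body_height <= 2.1:
        raise ValueError(f"body_height must lie in [1.4, 2.1] m, got {body_height}")
    rng = np.random.default_rng(seed)
    base = LabLayout(
        body_height=body_height, lane_gap=lane_gap, support_height=support_height
    )
    entities: list[SceneEntity] = []
    next_id = 0

    def add(label, center, size, lane=None, station=None):
        nonlocal next_id
        entities.append(
            SceneEntity(next_id, label, tuple(center), tuple(size), lane, station)
        )
        next_id += 1

    half_w = base.track_width / 2.0
    ball_d = 2 * _TENNIS_BALL_RADIUS
    for lane in ("right", "left"):
        lx = base.lane_center_x(lane)
        forced = int(rng.integers(0, base.hurdles_per_side))
        for i, station in enumerate(base.stations):
            level = 0.10 if i == forced else float(rng.choice(base.hurdle_height_levels))
            h = level * body_height
            add("hurdle", (lx, station, h / 2.0), (base.track_width, 0.04, h), lane, station)
            for sx in (-half_w, half_w):
                add(
                    "support",
                    (lx + sx, station, support_height / 2.0),
                    (0.05, 0.05, support_height),
                    lane,
                    station,
                )
                add(
                    "tennis_ball",
                    (lx + sx, station, support_height + _TENNIS_BALL_RADIUS),
                    (ball_d, ball_d, ball_d),
                    lane,
                    station,
                )
    for label, x, y, size in _DEFAULT_DISTRACTORS:
        jx, jy = rng.uniform(-0.1, 0.1, size=2)
        add(label, (x + jx, y + jy, size[2] / 2.0), size)

    return replace(base, entities=tuple(entities))


@dataclass(frozen=True)
class CameraModel:
    """Pinhole scene camera (defaults match a head-mounted eye-tracker camera)."""

    fx: float = 1100.0
    fy: float = 1100.0
    cx: float = 960.0
    cy: float = 540.0
    frame_size: FrameSize = FULL_HD
    fps: float = 24.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.fps <= 0:
            raise ValueError(f"frame rate must be positive, got {self.fps}")


@dataclass(frozen=True)
class CameraPose:
    """Camera position (metres) with yaw about z and pitch (radians)."""

    position: tuple[float, float, float]
    yaw: float = 0.0
    pitch: float = math.radians(-10.0)


def _camera_axes(pose: CameraPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cy, sy = math.cos(pose.yaw), math.sin(pose.yaw)
    cp, sp = math.cos(pose.pitch), math.sin(pose.pitch)
    right = np.array([cy, -sy, 0.0])
    forward = np.array([sy * cp, cy * cp, sp])
    down = np.cross(forward, right)
    return right, down, forward


def _project(
    points: np.ndarray, pose: CameraPose, camera: CameraModel
) -> tuple[np.ndarray, np.ndarray]:
    """Project Nx3 world points; returns (Nx2 pixel coords, N depth)."""
    right, down, forward = _camera_axes(pose)
    d = np.atleast_2d(points) - np.asarray(pose.position)
    xc = d @ right
    yc = d @ down
    zc = d @ forward
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.cx + camera.fx * xc / zc
        v = camera.cy + camera.fy * yc / zc
    return np.column_stack([u, v]), zc


def _entity_corners(e: SceneEntity) -> np.ndarray:
    c = np.asarray(e.center)
    h = np.asarray(e.size) / 2.0
    signs = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
    )
    return c + signs * h

def _project_entity_box(
    e: SceneEntity, pose: CameraPose, camera: CameraModel
) -> Optional[CornerBox]:
    """Clipped pixel bounding box of an entity, or None when not in view."""
    uv, zc = _project(_entity_corners(e), pose, camera)
    if zc.min() <= _NEAR_PLANE:
        return None
    fs = camera.frame_size
    x1 = max(float(uv[:, 0].min()), 0.0)
    x2 = min(float(uv[:, 0].max()), float(fs.width))
    y1 = max(float(uv[:, 1].min()), 0.0)
    y2 = min(float(uv[:, 1].max()), float(fs.height))
    if x2 - x1 <= 0.0 or y2 - y1 <= 0.0:
        return None
    return CornerBox(x1, y1, x2, y2)


def _lane_quads(layout: LabLayout, lane: str, step: float = 0.25) -> list[np.ndarray]:
    lx = layout.lane_center_x(lane)
    half = layout.track_width / 2.0
    edges = np.arange(0.0, layout.track_length + 1e-9, step)
    quads = []
    for y0, y1 in zip(edges, edges[1:]):
        quads.append(
            np.array(
                [
                    [lx - half, y0, 0.0],
                    [lx + half, y0, 0.0],
                    [lx + half, y1, 0.0],
                    [lx - half, y1, 0.0],
                ]
            )
        )
    return quads


def _fill_quad(arr: np.ndarray, uv: np.ndarray, value) -> None:
    rr, cc = _draw_polygon(uv[:, 1], uv[:, 0], shape=arr.shape)
    arr[rr, cc] = value


_CLASS_SHADES = {
    "hurdle": 235,  # white PVC pipe
    "tennis_ball": 205,
    "support": 120,
    "animate_distractor": 90,
    "bucket": 145,
    "computer": 60,
}
_BACKGROUND_SHADE = 165
_TRACK_SHADE = 25


@dataclass
class SyntheticFrame:
    """One rendered frame with its ground truth."""

    detections: list[Detection]
    entity_ids: list[Optional[int]]  # parallel to detections; None = crosshair
    mask: Optional[MaskImage] = None
    image: Optional[np.ndarray] = None


def render_frame(
    layout: LabLayout,
    pose: CameraPose,
    camera: CameraModel = CameraModel(),
    gaze_point: Optional[PixelPoint] = None,
    *,
    with_image: bool = True,
    with_mask: bool = True,
    crosshair_half_size: float = 12.0,
) -> SyntheticFrame:
    """Render one egocentric frame: annotations, track mask, flat-shaded image.

    Every entity in view contributes exactly one ground-truth detection
    (confidence 1, box clipped at the frame edges); the two lane ribbons are
    rasterized into the binary mask; a crosshair glyph is drawn at
    ``gaze_point`` (when given and inside the frame) and annotated under the
    crosshair class.
    """
    fs = camera.frame_size
    detections: list[Detection] = []
    entity_ids: list[Optional[int]] = []
    visible: list[tuple[SceneEntity, CornerBox, float]] = []
    for e in layout.entities:
        box = _project_entity_box(e, pose, camera)
        if box is None:
            continue
        _, zc = _project(np.asarray([e.center]), pose, camera)
        visible.append((e, box, float(zc[0])))
        detections.append(Detection(box=box, class_label=e.class_label, confidence=1.0))
        entity_ids.append(e.entity_id)

    mask_img: Optional[MaskImage] = None
    image: Optional[np.ndarray] = None
    lane_uvs: list[np.ndarray] = []
    if with_mask or with_image:
        for lane in ("right", "left"):
            for quad in _lane_quads(layout, lane):
                uv, zc = _project(quad, pose, camera)
                if zc.min() <= _NEAR_PLANE:
                    continue
                lane_uvs.append(uv)

    if with_mask:
        mask = np.zeros((fs.height, fs.width), dtype=bool)
        for uv in lane_uvs:
            _fill_quad(mask, uv, True)
        mask_img = MaskImage(pixels=mask)

    if with_image:
        image = np.full((fs.height, fs.width), _BACKGROUND_SHADE, dtype=np.uint8)
        for uv in lane_uvs:
            _fill_quad(image, uv, _TRACK_SHADE)
        # painter's order: far entities first
        for e, box, _ in sorted(visible, key=lambda t: -t[2]):
            shade = _CLASS_SHADES.get(e.class_label, 110)
            image[
                int(round(box.y1)) : max(int(round(box.y2)), int(round(box.y1)) + 1),
                int(round(box.x1)) : max(int(round(box.x2)), int(round(box.x1)) + 1),
            ] = shade

    if gaze_point is not None and 0 <= gaze_point.x <= fs.width and 0 <= gaze_point.y <= fs.height:
        h = crosshair_half_size
        box = CornerBox(
            max(gaze_point.x - h, 0.0),
            max(gaze_point.y - h, 0.0),
            min(gaze_point.x + h, float(fs.width)),
            min(gaze_point.y + h, float(fs.height)),
        )
        detections.append(Detection(box=box, class_label=CROSSHAIR_LABEL, confidence=1.0))
        entity_ids.append(None)
        if image is not None:
            gx = min(int(round(gaze_point.x)), fs.width - 1)
            gy = min(int(round(gaze_point.y)), fs.height - 1)
            x1, x2 = max(gx - int(h), 0), min(gx + int(h) + 1, fs.width)
            y1, y2 = max(gy - int(h), 0), min(gy + int(h) + 1, fs.height)
            image[max(gy - 1, 0) : gy + 2, x1:x2] = 255
            image[y1:y2, max(gx - 1, 0) : gx + 2] = 255

    return SyntheticFrame(
        detections=detections, entity_ids=entity_ids, mask=mask_img, image=image
    )


def simulate_walk(
    layout: LabLayout,
    speed: float,
    camera: CameraModel = CameraModel(),
    *,
    body_height: Optional[float] = None,
    start_y: float = 0.0,
    end_y: Optional[float] = None,
    pitch: float = math.radians(-10.0),
) -> list[CameraPose]:
    """Camera poses advancing along the right lane at ``speed`` m/s.

    One pose per frame at the camera's frame rate; eye height is
    0.936 x body height.  Pose count = ceil(path length / step).
    """
    if speed <= 0:
        raise ValueError(f"walking speed must be positive, got {speed}")
    bh = body_height if body_height is not None else layout.body_height
    eye_z = EYE_HEIGHT_RATIO * bh
    stop = end_y if end_y is not None else layout.track_length
    length = stop - start_y
    if length <= 0:
        return []
    step = speed / camera.fps
    n = math.ceil(length / step)
    return [
        CameraPose(position=(layout.right_lane_center_x, start_y + k * step, eye_z), pitch=pitch)
        for k in range(n)
    ]


# ---------------------------------------------------------------------------
# Gaze schedules and metric ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityFixation:
    entity_id: int


@dataclass(frozen=True)
class TrackFixation:
    lane: str = "right"
    ahead: float = 2.5  # metres ahead of the camera, clamped to the track


@dataclass(frozen=True)
class WorldPointFixation:
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class BlankFixation:
    """No usable gaze this segment (eye-tracker dropout)."""


FixationTarget = Union[EntityFixation, TrackFixation, WorldPointFixation, BlankFixation]


@dataclass(frozen=True)
class FixationSegment:
    start_frame: int
    end_frame: int  # exclusive
    target: FixationTarget


@dataclass(frozen=True)
class GazeSchedule:
    """Non-overlapping fixation segments covering a walk frame range."""

    segments: tuple[FixationSegment, ...]

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start_frame)
        for a, b in zip(segs, segs[1:]):
            if a.end_frame > b.start_frame:
                raise ValueError("fixation segments overlap")

    def target_at(self, frame: int) -> FixationTarget:
        for s in self.segments:
            if s.start_frame <= frame < s.end_frame:
                return s.target
        raise ValueError(f"gaze schedule does not cover frame {frame}")


def metric_row_rank(layout: LabLayout, station: float, cam_y: float) -> Optional[int]:
    """1-based rank of ``station`` among stations still ahead of the camera."""
    ahead = sorted(s for s in layout.stations if s > cam_y + 0.1)
    for rank, s in enumerate(ahead, start=1):
        if abs(s - station) < 1e-9:
            return rank
    return None


def _truth_for_target(
    layout: LabLayout,
    target: FixationTarget,
    pose: CameraPose,
    taxonomy: ClassTaxonomy,
) -> tuple[Optional[str], Optional[int], Optional[SideLabel], bool, AttentionState]:
    """(class, row, side, on_track, state) from the metric scene graph."""
    if isinstance(target, EntityFixation):
        e = layout.entity(target.entity_id)
        side = SideLabel.LEFT if e.center[0] < layout.gap_center_x else SideLabel.RIGHT
        row = (
            metric_row_rank(layout, e.station, pose.position[1])
            if e.station is not None
            else None
        )
        if not taxonomy.is_core(e.class_label):
            state = AttentionState.DISTRACTED_OBJECT
        elif side is SideLabel.LEFT:
            state = AttentionState.DISTRACTED_LEFT_TRACK
        elif row == 1:
            state = AttentionState.ATTEND_IMMEDIATE_OBSTACLE
        else:
            state = AttentionState.ATTEND_PLANNING
        return e.class_label, row, side, False, state
    if isinstance(target, TrackFixation):
        side = SideLabel.RIGHT if target.lane == "right" else SideLabel.LEFT
        state = (
            AttentionState.TRACK_SURFACE
            if side is SideLabel.RIGHT
            else AttentionState.DISTRACTED_LEFT_TRACK
        )
        return None, None, None, True, state
    if isinstance(target, WorldPointFixation):
        return None, None, None, False, AttentionState.UNCLASSIFIED
    return None, None, None, False, AttentionState.INVALID_GAZE


def _target_world_point(
    layout: LabLayout, target: FixationTarget, pose: CameraPose
) -> Optional[np.ndarray]:
    if isinstance(target, EntityFixation):
        return np.asarray(layout.entity(target.entity_id).center)
    if isinstance(target, TrackFixation):
        y = min(max(pose.position[1] + target.ahead, 0.2), layout.track_length - 0.2)
        return np.array([layout.lane_center_x(target.lane), y, 0.0])
    if isinstance(target, WorldPointFixation):
        return np.array([target.x, target.y, target.z])
    return None


def simulate_gaze(
    layout: LabLayout,
    poses: Sequence[CameraPose],
    camera: CameraModel,
    schedule: GazeSchedule,
    taxonomy: Optional[ClassTaxonomy] = None,
    jitter_px: float = 2.0,
    seed: int = 0,
) -> tuple[list[GazeSample], list[AttentionRecord]]:
    """Scripted gaze samples plus metric ground-truth attention records.

    Each frame's gaze point is the projection of the scheduled fixation
    target plus isotropic Gaussian jitter (sigma ``jitter_px``); the
    ground-truth record is derived from the metric scene graph (true target
    identity, true row by along-walk distance, true side by lane), not from
    the image-space pipeline.  Raises if the schedule does not cover every
    frame.
    """
    taxonomy = taxonomy or ClassTaxonomy.default()
    rng = np.random.default_rng(seed)
    fs = camera.frame_size
    samples: list[GazeSample] = []
    records: list[AttentionRecord] = []
    for i, pose in enumerate(poses):
        target = schedule.target_at(i)
        wp = _target_world_point(layout, target, pose)
        valid = wp is not None
        gx = gy = 0.0
        if valid:
            uv, zc = _project(wp[None, :], pose, camera)
            if zc[0] <= _NEAR_PLANE:
                valid = False
            else:
                gx = float(uv[0, 0]) + float(rng.normal(0.0, jitter_px))
                gy = float(uv[0, 1]) + float(rng.normal(0.0, jitter_px))
                valid = 0.0 <= gx <= fs.width and 0.0 <= gy <= fs.height
        sample = GazeSample(i, PixelPoint(gx, gy), valid=valid)
        samples.append(sample)

        if not valid:
            records.append(
                AttentionRecord(i, None, None, None, None, None, False, AttentionState.INVALID_GAZE)
            )
            continue
        cls, row, side, on_track, state = _truth_for_target(layout, target, pose, taxonomy)
        records.append(AttentionRecord(i, gx, gy, cls, row, side, on_track, state))
    return samples, records


def default_gaze_schedule(n_frames: int, layout: LabLayout) -> GazeSchedule:
    """A canonical fixation script cycling through every attention state.

    Cycles: nearest right hurdle -> track surface ahead -> second right
    hurdle -> nearest left hurdle (opposite lane) -> animate distractor ->
    nearest right tennis ball -> off-track wall point -> gaze dropout.
    """
    s1 = layout.stations[0]
    s2 = layout.stations[min(1, len(layout.stations) - 1)]
    targets: list[FixationTarget] = [
        EntityFixation(layout.find_entity("hurdle", "right", s1).entity_id),
        TrackFixation("right", 2.5),
        EntityFixation(layout.find_entity("hurdle", "right", s2).entity_id),
        EntityFixation(layout.find_entity("hurdle", "left", s1).entity_id),
        EntityFixation(layout.find_entity("animate_distractor").entity_id),
        EntityFixation(layout.find_entity("tennis_ball", "right", s1).entity_id),
        WorldPointFixation(5.0, 8.5, 2.0),
        BlankFixation(),
    ]
    seg_len = max(1, math.ceil(n_frames / len(targets)))
    segments: list[FixationSegment] = []
    for i, t in enumerate(targets):
        start = i * seg_len
        if start >= n_frames:
            break
        segments.append(FixationSegment(start, min(start + seg_len, n_frames), t))
    return GazeSchedule(segments=tuple(segments))


def nearest_row_gap_px(
    layout: LabLayout, pose: CameraPose, camera: CameraModel
) -> Optional[float]:
    """Pixel gap between the two nearest ahead row lines (ball height).

    The row line of a station is the projected image y of a tennis-ball
    centre at that station.  Returns None when fewer than two stations lie
    ahead of the camera.
    """
    cam_y = pose.position[1]
    ahead = sorted(s for s in layout.stations if s > cam_y + 0.1)
    if len(ahead) < 2:
        return None
    ball_z = layout.support_height + _TENNIS_BALL_RADIUS
    pts = np.array([[layout.right_lane_center_x, s, ball_z] for s in ahead[:2]])
    uv, zc = _project(pts, pose, camera)
    if zc.min() <= _NEAR_PLANE:
        return None
    return float(uv[0, 1] - uv[1, 1])


def generate_dataset(
    out_dir: str | Path,
    n_frames: int,
    seed: int,
    *,
    layout: Optional[LabLayout] = None,
    camera: Optional[CameraModel] = None,
    body_height: float = 1.66,
    speed: float = 1.2,
    start_y: float = -2.2,
    schedule: Optional[GazeSchedule] = None,
    taxonomy: Optional[ClassTaxonomy] = None,
    jitter_px: float = 2.0,
    overwrite: bool = False,
) -> dict:
    """Write a complete synthetic dataset and return its manifest.

    Layout: ``frames/<id>.png``, ``annotations/<id>.txt``, ``masks/<id>.png``,
    ``gaze.csv``, ``truth.csv``, ``manifest.json``.  All randomness flows from
    ``seed``, so identical seeds give byte-identical datasets.  The walk
    starts ``start_y`` metres before the track (negative = before the first
    lane metre) so the obstacle rows stay ahead and row-separable.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    taxonomy = taxonomy or ClassTaxonomy.default()
    camera = camera or CameraModel()
    layout = layout or build_default_layout(body_height=body_height, seed=seed)
    poses = simulate_walk(layout, speed, camera, start_y=start_y)[:n_frames]
    if len(poses) < n_frames:
        raise ValueError(
            f"walk yields only {len(poses)} poses for {n_frames} requested frames"
        )
    schedule = schedule or default_gaze_schedule(n_frames, layout)
    samples, truth = simulate_gaze(
        layout, poses, camera, schedule, taxonomy, jitter_px=jitter_px, seed=seed
    )

    # Scene validity: the two nearest row lines must be separable by the
    # default clustering threshold while approaching the first row.
    for pose in poses:
        dist = layout.stations[0] - pose.position[1]
        if 1.5 <= dist <= 4.5:
            gap = nearest_row_gap_px(layout, pose, camera)
            if gap is not None and gap <= 50.0:
                raise ValueError(
                    f"scene invalid: nearest row lines only {gap:.1f} px apart "
                    f"at {dist:.2f} m from the first row"
                )

    frames_dir = out / "frames"
    ann_dir = out / "annotations"
    masks_dir = out / "masks"
    for d in (frames_dir, ann_dir, masks_dir):
        d.mkdir(parents=True, exist_ok=True)

    class_counts: dict[str, int] = {}
    for i, pose in enumerate(poses):
        frame_id = f"frame_{i:06d}"
        gaze_pt = samples[i].point if samples[i].valid else None
        frame = render_frame(layout, pose, camera, gaze_point=gaze_pt)
        iio.imwrite(frames_dir / f"{frame_id}.png", frame.image)
        write_mask(frame.mask, masks_dir / f"{frame_id}.png")
        write_yolo_annotation(
            frame.detections, camera.frame_size, taxonomy, ann_dir / f"{frame_id}.txt"
        )
        for det in frame.detections:
            class_counts[det.class_label] = class_counts.get(det.class_label, 0) + 1

    write_gaze_csv(samples, out / "gaze.csv")
    from .attention import write_context_csv

    write_context_csv(truth, out / "truth.csv")

    manifest = {
        "n_frames": n_frames,
        "seed": seed,
        "speed_m_per_s": speed,
        "start_y_m": start_y,
        "body_height_m": layout.body_height,
        "class_counts": dict(sorted(class_counts.items())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
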