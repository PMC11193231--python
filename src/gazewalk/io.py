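"""Readers and writers for the dataset file formats.

The on-disk layout mirrors the usual detector-training convention: an
``images`` folder of full-resolution PNG frames with an ``annotations``
folder of same-stem ``.txt`` files, one line per object in normalized
``class_id x_mid y_mid width height`` form; binary track masks as
black/white PNGs; and a hardware-neutral gaze CSV with columns
``frame_index, gaze_x, gaze_y`` in pixel units (blank coordinates mark
frames without a valid gaze estimate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .gaze import GazeSample
from .geometry import (
    ClassTaxonomy,
    CornerBox,
    Detection,
    FrameSize,
    PixelPoint,
    YoloBox,
    corner_to_yolo,
    yolo_to_corner,
)

__all__ = [
    "FrameAnnotation",
    "MaskImage",
    "read_yolo_annotation",
    "write_yolo_annotation",
    "read_mask",
    "write_mask",
    "read_gaze_csv",
    "write_gaze_csv",
]

#: 8-bit grayscale threshold above which a mask pixel counts as foreground.
MASK_BINARIZE_THRESHOLD = 128


@dataclass
class FrameAnnotation:
    """Ground-truth annotation of one frame (confidence fixed at 1)."""

    frame_id: str
    detections: list[Detection] = field(default_factory=list)
    image_path: Path | None = None


@dataclass
class MaskImage:
    """Binary segmentation mask; True = walking track."""

    pixels: np.ndarray  # 2-D bool array, shape (height, width)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")

    @property
    def frame_size(self) -> FrameSize:
        h, w = self.pixels.shape
        return FrameSize(w, h)


def read_yolo_annotation(
    path: str | Path, fs: FrameSize, taxonomy: ClassTaxonomy
) -> FrameAnnotation:
    """Parse one annotation text file into a FrameAnnotation.

    Each non-empty line must hold five whitespace-separated numeric fields
    (class id + normalized box).  Malformed lines and class ids outside the
    taxonomy raise ValueError naming the offending line.
    """
    path = Path(path)
    detections: list[Detection] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 5 fields, got {len(fields)}: {line!r}"
            )
        try:
            class_id = int(fields[0])
            x_mid, y_mid, w, h = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field: {line!r}") from exc
        try:
            label = taxonomy.label(class_id)
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: {exc.args[0]}") from None
        try:
            box = yolo_to_corner(YoloBox(class_id, x_mid, y_mid, w, h), fs)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        detections.append(Detection(box=box, class_label=label, confidence=1.0))
    return FrameAnnotation(frame_id=path.stem, detections=detections)


def write_yolo_annotation(
    ann: FrameAnnotation | Sequence[Detection],
    fs: FrameSize,
    taxonomy: ClassTaxonomy,
    path: str | Path,
) -> None:
    """Write detections as normalized annotation lines (6-decimal fractions)."""
    detections = ann.detections if isinstance(ann, FrameAnnotation) else list(ann)
    lines = []
    for det in detections:
        yb = corner_to_yolo(det.box, fs, class_id=taxonomy.index(det.class_label))
        lines.append(
            f"{yb.class_id} {yb.x_mid:.6f} {yb.y_mid:.6f} {yb.w:.6f} {yb.h:.6f}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_mask(path: str | Path, fs: FrameSize) -> MaskImage:
    """Load a binary track mask from a raster file.

    Grayscale values >= 128 map to foreground; this tolerates anti-aliased
    edges in masks exported by annotation tools.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to grayscale by channel mean
        arr = arr[..., :3].mean(axis=2)
    h, w = arr.shape
    if (w, h) != (fs.width, fs.height):
        raise ValueError(
            f"mask {path} has size {w}x{h}, expected {fs.width}x{fs.height}"
        )
    return MaskImage(pixels=arr >= MASK_BINARIZE_THRESHOLD)


def write_mask(mask: MaskImage, path: str | Path) -> None:
    """Write a mask as an 8-bit black/white PNG (foreground = 255)."""
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def read_gaze_csv(path: str | Path, fs: FrameSize) -> list[GazeSample]:
    """Read a per-frame gaze stream.

    Expected header: ``frame_index, gaze_x, gaze_y`` (pixel units).  Blank
    coordinates, or coordinates outside the frame, yield ``valid = False``
    samples (their point is kept verbatim, or (0, 0) when blank).  Frame
    indices must be strictly increasing.
    """
    path = Path(path)
    samples: list[GazeSample] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"frame_index", "gaze_x", "gaze_y"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header columns {sorted(required)}")
        prev_index = None
        for rownum, row in enumerate(reader, start=2):
            try:
                frame_index = int(row["frame_index"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {rownum}: non-integer frame_index {row['frame_index']!r}"
                ) from None
            if prev_index is not None and frame_index <= prev_index:
                raise ValueError(
                    f"{path}: row {rownum}: frame_index {frame_index} not "
                    f"strictly increasing after {prev_index}"
                )
            prev_index = frame_index
            gx_raw, gy_raw = row["gaze_x"].strip(), row["gaze_y"].strip()
            if not gx_raw or not gy_raw:
                samples.append(
                    GazeSample(frame_index, PixelPoint(0.0, 0.0), valid=False)
                )
                continue
            try:
                gx, gy = float(gx_raw), float(gy_raw)
            except ValueError:
                raise ValueError(
                    f"{path}: row {rownum}: non-numeric gaze coordinate "
                    f"({gx_raw!r}, {gy_raw!r})"
                ) from None
            in_frame = 0.0 <= gx <= fs.width and 0.0 <= gy <= fs.height
            samples.append(GazeSample(frame_index, PixelPoint(gx, gy), valid=in_frame))
    return samples


def write_gaze_csv(samples: Sequence[GazeSample], path: str | Path) -> None:
    """Write a gaze stream; invalid samples get blank coordinates."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "gaze_x", "gaze_y"])
        for s in samples:
            if s.valid:
                writer.writerow([s.frame_index, f"{s.point.x:.3f}", f"{s.point.y:.3f}"])
            else:
                writer.writerow([s.frame_index, "", ""])
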