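"""End-to-end drivers: contextualize a dataset folder or an in-memory walk."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from .attention import (
    AttentionRecord,
    SequenceSummary,
    contextualize_sequence,
)
from .gaze import GazeSample
from .geometry import ClassTaxonomy, FrameSize, FULL_HD
from .io import MaskImage, read_gaze_csv, read_mask, read_yolo_annotation
from .spatial import DEFAULT_ROW_GAP_PX

__all__ = ["contextualize_dataset", "contextualize_synthetic_walk"]


def _frame_id(index: int) -> str:
    return f"frame_{index:06d}"


def contextualize_dataset(
    annotations_dir: str | Path,
    gaze_csv: str | Path,
    masks_dir: Optional[str | Path] = None,
    fs: FrameSize = FULL_HD,
    taxonomy: Optional[ClassTaxonomy] = None,
    fps: float = 24.0,
    gap_threshold: float = DEFAULT_ROW_GAP_PX,
) -> tuple[list[AttentionRecord], SequenceSummary]:
    """Run the full contextualization pipeline over an on-disk dataset.

    ``annotations_dir`` holds one ``frame_<index>.txt`` per frame (detector
    output or ground truth); the gaze CSV drives which frames are processed.
    Frames without an annotation file contribute no detections.  When
    ``masks_dir`` is given, the per-frame track mask enables side labelling
    and track-surface overlap.
    """
    taxonomy = taxonomy or ClassTaxonomy.default()
    annotations_dir = Path(annotations_dir)
    masks_path = Path(masks_dir) if masks_dir is not None else None
    samples = read_gaze_csv(gaze_csv, fs)

    def frames():
        for s in samples:
            fid = _frame_id(s.frame_index)
            ann_file = annotations_dir / f"{fid}.txt"
            dets = (
                read_yolo_annotation(ann_file, fs, taxonomy).detections
                if ann_file.exists()
                else []
            )
            mask: Optional[MaskImage] = None
            if masks_path is not None:
                mask_file = masks_path / f"{fid}.png"
                if mask_file.exists():
                    mask = read_mask(mask_file, fs)
            yield dets, s, mask

    return contextualize_sequence(frames(), taxonomy, fps=fps, gap_threshold=gap_threshold)


def contextualize_synthetic_walk(
    layout,
    poses,
    camera,
    gaze_samples: Sequence[GazeSample],
    taxonomy: Optional[ClassTaxonomy] = None,
    gap_threshold: float = DEFAULT_ROW_GAP_PX,
) -> tuple[list[AttentionRecord], SequenceSummary]:
    """Run the pipeline on an in-memory synthetic walk (oracle detections).

    Uses the generator's ground-truth annotations and masks directly as
    detector/segmenter output, skipping raster encode/decode; this is the
    closed-loop configuration for validating the contextualization mechanics.
    """
    from .synthetic import render_frame

    taxonomy = taxonomy or ClassTaxonomy.default()

    def frames():
        for pose, gz in zip(poses, gaze_samples):
            frame = render_frame(
                layout,
                pose,
                camera,
                gaze_point=gz.point if gz.valid else None,
                with_image=False,
                with_mask=True,
            )
            yield frame.detections, gz, frame.mask

    return contextualize_sequence(frames(), taxonomy, fps=camera.fps, gap_threshold=gap_threshold)
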