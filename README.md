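# gazewalk

Automated contextualization of visual attention in egocentric video from
lab-based walking trials.

Fall-risk walking protocols often have participants cross low hurdles on a
marked walking loop while wearing video eye-tracking glasses. The glasses
record what the lab looks like from the walker's perspective and where the
walker is looking in each frame, but turning that stream into something
clinically useful — *was the walker attending the upcoming hurdle, scanning
the path, or distracted?* — normally means hours of manual frame labelling.

`gazewalk` automates that step. Given, per frame,

- object detections (hurdles, tennis balls marking the crossing opening,
  their supports, and lab clutter) in the normalized
  `class x_mid y_mid w h` annotation format,
- a gaze point in pixel coordinates (or a detected eye-tracker crosshair),
- and optionally a binary segmentation mask of the walking track,

it resolves the gaze target (hit-testing the gaze point against detection
boxes), clusters the tennis balls into obstacle **rows** by their vertical
image coordinate (a new row starts at a ≥ 50 px gap), assigns every object a
row (nearest row line; row 1 is the closest), fits the **separator line**
through the gap between the two track lanes in the mask (per-scanline gap
midpoints + least squares, `x = a·y + b`), labels objects **left** (opposite
lane — a distraction) or **right** (active lane — task-relevant), and fuses
everything into one per-frame attention state:

`ATTEND_IMMEDIATE_OBSTACLE`, `ATTEND_PLANNING`, `TRACK_SURFACE`,
`DISTRACTED_LEFT_TRACK`, `DISTRACTED_OBJECT`, `UNCLASSIFIED`,
`INVALID_GAZE`.

The package also provides:

- the standard detector/segmenter validation metrics (greedy IoU ≥ 0.5
  matching, all-point interpolated AP and mAP50, confusion matrix with a
  background class, pixelwise mask IoU) — `gazewalk.evaluation`;
- a reference implementation of the size-weighted, class-balanced focal
  loss `-α (n_y/n) (1-p)^γ ln p` with per-class size weights
  `w_j = s/h_j + ε` — `gazewalk.loss`;
- a seeded **synthetic lab generator** (`gazewalk.synthetic`): a metric
  model of a two-sided 12 m × 0.92 m walking loop with three hurdle rows per
  side every 3 m (hurdle heights drawn from {5, 7.5, 10, 12.5}% of body
  height), tennis balls on supports flanking each row, off-track
  distractors, a walking pinhole camera, flat-shaded frames, ground-truth
  annotations and track masks, scripted gaze schedules, and metric
  ground-truth attention labels for closed-loop validation.

## Worked example

Generate a 48-frame synthetic walk, contextualize it with the pipeline, and
look at the output:

```sh
$ gazewalk simulate --out demo --frames 48 --seed 7
{
  "n_frames": 48,
  "seed": 7,
  ...
  "class_counts": {
    "animate_distractor": 48,
    ...
    "hurdle": 288,
    "support": 576,
    "tennis_ball": 576
  }
}

$ gazewalk contextualize --annotations demo/annotations \
    --gaze demo/gaze.csv --masks demo/masks --out demo/context.csv
wrote 48 records to demo/context.csv
  ATTEND_IMMEDIATE_OBSTACLE: 12
  ATTEND_PLANNING: 6
  DISTRACTED_LEFT_TRACK: 6
  DISTRACTED_OBJECT: 6
  INVALID_GAZE: 6
  TRACK_SURFACE: 6
  UNCLASSIFIED: 6
```

The state counts mirror the scripted gaze schedule: the synthetic walker
fixates the nearest right-lane hurdle (immediate obstacle), the track
surface ahead, a hurdle further ahead (planning), an opposite-lane hurdle
(left-track distraction), an off-track person (object distraction), the
nearest right tennis ball, a bare wall point, and finally the eye tracker
drops out. The contextual CSV holds one row per frame:

```
frame_index,gaze_x,gaze_y,target_class,target_row,target_side,on_track,state
0,960.002,652.195,hurdle,1,right,true,ATTEND_IMMEDIATE_OBSTACLE
```

i.e. at frame 0 the gaze sits on a hurdle in row 1 (the nearest row) on the
right (active) lane, so the walker is attending the immediate obstacle.

The focal-loss demo evaluates the loss at a point
(here α = 0.25, γ = 2, n_y/n = 0.5, p = 0.9):

```sh
$ gazewalk loss-demo --p 0.9 --freq 50/100
0.0001317006446
```

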