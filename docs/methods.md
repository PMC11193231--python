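# Methods

## Problem setting

A participant walks a two-sided loop in a gait lab: two parallel straight
lanes (each 12 m long and 0.92 m wide) with three obstacle stations per lane
every 3 m. Each station is a low hurdle spanning the lane, flanked by a
tennis ball on a support at each lane edge (the balls mark the horizontal
opening the walker judges before crossing). Head-mounted eye-tracking
glasses record egocentric video (1920 × 1080 px, 24 fps) and a per-frame
gaze point. The package answers, per frame: *what is the walker looking at,
in which obstacle row, on which side of the loop — and what does that imply
about their attention?*

The package deliberately does not train detectors or segmenters. It consumes
their outputs (boxes, masks, points) behind a small data contract, so any
detector can be plugged in; the synthetic generator doubles as a perfect
"oracle detector" for closed-loop validation of the contextualization
mechanics themselves.

## Coordinate and box conventions

Image origin top-left, x rightward, y downward, pixel units. Boxes are
real-valued closed intervals; point-in-box is boundary-inclusive, so a gaze
pixel on a box edge counts as a hit — conservative in the sense that it
favours detecting attention. Normalized annotation boxes store fractions of
the frame in [0, 1]. IoU of two zero-area boxes is defined as 0 (avoids
0/0). Non-maximum suppression is greedy and class-wise, ordered by
descending confidence with ties broken by larger area then input order;
suppression requires IoU strictly above the threshold.

The default taxonomy has 18 classes. Seven are fixed by the protocol
(hurdle, tennis_ball, support, animate_distractor, bucket, computer,
eye_tracker_crosshair); the remaining eleven are configurable lab-clutter
names, since only the core/non-core distinction affects the pipeline. Core
classes are tennis_ball, support, hurdle.

## Gaze-target resolution

All detections whose box contains the gaze point are candidate targets,
ordered by ascending box area. The primary target is the smallest-area hit:
a nested box is a more specific answer than the box around it. Exact area
ties fall back to core-object priority (hurdle > tennis_ball > support >
other), then input order. Crosshair detections mark the gaze point itself
and are never eligible as targets; when no external gaze stream is supplied,
the centre of the highest-confidence crosshair detection is used as the
gaze point, but an external stream always takes precedence.

Track overlap is a single mask lookup at the gaze pixel, rounding
half-away-from-zero (sub-pixel gaze is not meaningful at mask resolution);
an edge coordinate that rounds one past the last row/column is clamped back
inside.

## Obstacle rows

Tennis balls are clustered into rows by their box y-midpoints: sort, then
start a new row whenever the gap between consecutive midpoints is ≥ the
threshold (default 50 px; a gap strictly below it keeps the same row). The
row line is the mean member y-midpoint. Row 1 is the row with the *largest*
row line: in an egocentric view, closer floor objects project lower in the
frame. Any object is assigned the row minimizing |y-midpoint − row line|,
with exact ties going to the nearer row — the conservative choice when the
question is whether the walker sees the immediate obstacle. "Y position" of
a ball is its box midpoint rather than an edge; midpoints are stable under
symmetric box jitter.

## Track separator and side labels

On every mask scanline showing exactly two foreground runs (the two lanes),
the midpoint between the left run's right edge and the right run's left edge
is recorded; a least-squares line `x = a·y + b` is fitted through the
midpoints. Least squares over all qualifying scanlines is robust to ragged
mask edges; scanlines with one run (lane clipped out of frame) or more than
two runs (mask noise) are skipped. The separator is declared unidentifiable
when fewer than 30% of foreground scanlines qualify (or fewer than two in
total). An object is *left* iff its x-midpoint is left of the separator
evaluated at its y-midpoint (clamped into the fitted y-range); the boundary
counts as right. The active lane is always on the walker's right, so left =
opposite lane = distraction.

## Attention cascade

First match wins:

1. invalid gaze → `INVALID_GAZE`
2. core target on the left → `DISTRACTED_LEFT_TRACK`
3. core target on the right, row 1 → `ATTEND_IMMEDIATE_OBSTACLE`
4. core target on the right, other row → `ATTEND_PLANNING`
5. non-core target → `DISTRACTED_OBJECT`
6. no target, gaze on track, right of separator → `TRACK_SURFACE`
7. no target, gaze on track, left → `DISTRACTED_LEFT_TRACK`
8. otherwise → `UNCLASSIFIED`

Two degradations are deliberate. Without a usable mask the side is treated
as right: the pipeline never reports a left-lane distraction without mask
evidence. A core target whose row cannot be established (no ball rows in
view) maps to `ATTEND_PLANNING`: the object is task-relevant but its
immediacy is unknown. Dwell time is consecutive-frame run length on the same
target class times the frame period (1/24 s by default); no saccade/fixation
event filtering is applied.

## Evaluation metrics

Matching is greedy and one-to-one: predictions in descending confidence each
take the highest-IoU unmatched same-class truth with IoU ≥ 0.5. Average
precision uses **all-point** interpolation (area under the precision
envelope of the confidence-ranked PR staircase); mAP50 averages AP over the
classes present in the ground truth — classes the detector never had to
find neither dilute nor inflate the mean. Precision/recall are
micro-averaged over all pooled detections. The confusion matrix uses
class-*agnostic* spatial matching (so a well-localized box with the wrong
label lands off-diagonal) with a confidence floor of 0.25 and an explicit
background row (spurious predictions) and column (missed truths). Mask IoU
is pixelwise; two empty masks score 1 (the empty prediction is vacuously
correct). An mAP50-95 sweep (0.50:0.05:0.95) reuses the same machinery.

## Focal loss

The per-sample loss is `-α (n_y/n) (1-p)^γ ln p` with natural log and `p`
clamped into `[ε, 1]` (ε defaults to 1e-7 and is shared with the size-weight
constant). Only the frequency ratio matters, so rescaling the training set
leaves the loss unchanged. Size weights are `w_j = s/h_j + ε`, applied per
anchor as `focal × sqrt(w_j/h_ij)`; the total is the plain sum over classes.
The batch-mean-size and size-weight definitions reference each other; the
package resolves the circularity with one documented sequential pass
(weights initialized to 1, then recomputed once from the resulting mean
size) while keeping the direct per-sample loss usable on its own. This is an
interpretation, not the only possible reading, which is why both entry
points are public.

## Synthetic lab generator

World coordinates are metres: x lateral (positive right), y along the walk,
z up. The right (active) lane is centred on x = 0; the left lane lies across
a 1.0 m gap (the lane gap and ball/support offsets are configuration, not
protocol values). Hurdle heights are drawn per station from
{5, 7.5, 10, 12.5}% of body height with one station per side forced to the
10% level. Supports are 0.15 m posts at the lane edges with a 33 mm-radius
ball on top; distractors (a person, a bucket, a computer) stand off-track
with small seeded positional jitter.

The camera is an ideal pinhole at eye height 0.936 × body height
(anthropometric constant) with focal length 1100 px (≈ 82° horizontal field
of view), principal point at the frame centre, pitch −10° (typical
head-mounted tilt), walking the right lane centreline at a constant speed
(default 1.2 m/s, one pose per frame at 24 fps). All defaults are
configurable.

Rendering is flat-shaded rasterization: lane ribbons are subdivided into
0.25 m quads, projected and polygon-filled (dark on the image, foreground in
the mask); each entity contributes its projected, frame-clipped 2-D bounding
box as a ground-truth annotation and a shaded rectangle in the image; a
crosshair glyph is drawn at the scheduled gaze point and annotated under the
crosshair class. No textures, lighting, or occlusion — the pipeline consumes
boxes, masks, and points, not photometric content, so photorealism would add
nothing to what the tests can show.

Gaze schedules are explicit fixation segments (entity / track point ahead /
fixed world point / dropout). The scheduled target's projection plus
isotropic Gaussian jitter (σ = 2 px, an optimistic but typical eye-tracker
precision) is the gaze sample; the ground-truth attention record is computed
from the *metric* scene graph — true target identity, true row by along-walk
distance among stations still ahead, true side by lane membership — never
from the image-space pipeline under test. The default walk starts 2.2 m
before the track so all three rows stay ahead of the camera, and the
generator validates that the two nearest projected row lines stay more than
50 px apart while approaching the first row (checked for poses 1.5–4.5 m
before it). Farther row pairs may legitimately compress below 50 px near the
horizon and merge under clustering; this is harmless for the attention
semantics because merged far rows are all "planning" rows, but it is the
main known limitation of the single-threshold row model.

### What the generator does and does not emulate

It reproduces the protocol geometry, the annotation/mask/gaze file formats,
egocentric perspective, and scripted attention behaviour with per-frame
ground truth — enough to validate the contextualization mathematics end to
end. It does not emulate detector noise (missed/spurious/jittered boxes),
motion blur, lighting variation, head rotation dynamics, gait-induced camera
oscillation, occlusion, or saccade kinematics. Passing closed-loop tests
therefore demonstrates the correctness of the contextualization mechanics on
clean inputs, not the robustness of any particular detector in real footage.

## Problem sizes and numerical choices

Closed-loop validation uses ten seeded walks of ~61 frames each
(≈ 600 frames), 500 seeded row configurations, 100 separator frames, 50
oracle-detector frames, and 10,000-case oracle sweeps for the geometry
primitives — sizes chosen to exercise every code path with tight tolerances
while keeping the whole suite fast on a laptop. Determinism everywhere flows
from a single integer seed (`numpy.random.default_rng`); file outputs
(PNG/CSV/JSON) are byte-reproducible. Floating-point comparisons in the
oracles use absolute tolerances of 1e-9 (geometry) and 1e-12 (AP), both far
below pixel resolution.

## Known limitations

- The row model is 1-D (image y) with a fixed pixel threshold; it assumes
  the camera looks roughly along the track, as in the protocol.
- Side classification needs both lanes visible on enough scanlines; with one
  lane out of frame the pipeline degrades to side = right by design.
- Attention semantics are per-frame; no temporal smoothing or
  fixation-event segmentation is applied.
- The end-to-end accuracy figure is measured on synthetic walks with oracle
  detections; real-detector performance must be evaluated separately with
  `gazewalk.evaluation`.
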