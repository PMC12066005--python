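# Methods

## The assay and the scoring problem

A single *Drosophila* is housed in a glass culture vial whose usable
height — stopper to floor (or food surface) — is set to 3 cm, filmed
from the side at 30 frames/s under infrared illumination.  At the
standard camera distance the 3 cm span corresponds to roughly 325
pixel rows, giving a calibration of 3/325 cm per pixel.

A *fall* is the fly dropping rapidly from a standing position on the
vial wall to the bottom surface.  The descent takes a small fraction of
a second, fast enough that a per-frame detector loses the animal: the
fly blurs into a faint streak and is next seen on the floor.  A fall
therefore appears in the tracked trajectory not as a dense downward
trace but as a *gap* whose last detection is high and whose next
detection is low.  That gap signature is what the scorer keys on.

Image coordinates are used throughout: origin top-left, y increasing
downward.  "Upper half of the vial" means `y < top_y + 0.5*(bottom_y -
top_y)`; a fall has positive Δy.  Timestamps are `frame_index / fps`
seconds from recording start; hour *k* is the half-open interval
`[3600k, 3600(k+1))` so a boundary event is counted exactly once.

## Detection

The detector solves a deliberately narrow problem: one bright animal on
a dark, static background.  A background model is built as the
per-pixel median of `bg_frames` (default 25) uniformly spaced frames;
the median suppresses the fly, which occupies any given pixel only
transiently, while retaining static structure such as the bright glare
band cast by the stopper.  Each frame is then scored as
`|frame - background| >= intensity_threshold` (default 25 of 255), the
thresholded mask is decomposed into 8-connected components, and the
largest component of area at least `min_area` (default 9 px², about one
fly at this magnification) becomes the detection.  Its bounding box and
centroid are reported with confidence `min(1, area / (4*min_area))`.
No detection is a valid per-frame outcome, not an error: dropout *is*
the fall signature.  Detections whose centroid lies outside
`[top_y, bottom_y]` are discarded as reflections or edge artifacts.

The fly's position is the component (or box) **centroid**, not a box
edge.  Any external detector that can emit a per-frame CSV of
`frame, x, y, width, height, confidence` can be scored through the same
pipeline via `read_trajectory`; downstream code is agnostic to how the
boxes were produced.

## Fall scoring

Consecutive detection pairs `(d_i, d_{i+1})` are scanned; a pair is
scored as one fall when all of the following hold:

1. **rapid**: `t_{i+1} - t_i <= max_fall_duration_s` (default 1.0 s);
2. **large downward displacement**: `cy_{i+1} - cy_i >= y_threshold_px`
   (default 60 px; 160 px is the strict setting);
3. **ends at the bottom**: `cy_{i+1}` lies in the bottom
   `bottom_fraction` (default 0.25) of the vial height;
4. optionally, **starts in the upper half** (`require_upper_start`,
   default off) — the definition used for manual ground-truth
   annotation.  The automated scorer runs with this off, because
   genuine falls also start below the half-height line; the strict
   160 px threshold is what removes those short drops when the manual
   definition must be reproduced.

Each qualifying pair yields exactly one event, so events cannot
overlap; a multi-bounce descent whose sub-drops are individually below
threshold is not scored, and one whose sub-drops individually qualify
is scored per pair.  The event timestamp is the time of the **last
detection before the gap** — the physically meaningful onset, and
compatible with the ±1 s matching tolerance either way.

`max_fall_duration_s` bounds how long a gap may last and still be
called rapid.  1.0 s is comfortably above the longest observed descent
(~0.5 s) and at the matching tolerance, so a gap that long cannot
shift a match across the tolerance boundary.

**Total movement** is the trajectory path length
`Σ sqrt(Δcx² + Δcy²)` over successive detections, in pixels.  Pairs
spanning gaps are included: the displacement across a fall is real
movement, and the defining sum has no exclusions.

**Normalization.**  Falls per hour confound propensity to fall with
opportunity: an active fly climbs more and hence can fall more.  Each
hour's movement is converted to a *relative unit* — that hour's
movement divided by the mean hourly movement over hours with any
movement — and the hourly fall count is divided by its relative unit.
This keeps normalized values on the falls-per-hour scale (an
average-activity hour keeps its raw count).  An hour with zero
movement and zero falls normalizes to 0; an hour claiming falls but no
movement is rejected as inconsistent, since a scored fall contributes
displacement by construction.

## Evaluation

Predicted event timestamps are matched one-to-one against manually
annotated ground-truth timestamps; a pair is admissible when
`|p - t| <= 1.0 s`.  Matching is maximum-cardinality, computed by a
greedy two-pointer sweep over the sorted lists, which is optimal for a
symmetric scalar tolerance (verified in the test suite against
exhaustive bipartite maximum matching); ties resolve to the
earliest-time pairing.  Unmatched predictions are false positives,
unmatched truths false negatives.

Both FP% and FN% are reported as percentages of **predicted** falls.
A FN rate per ground truth would be the more conventional choice; the
predicted-fall denominator is used so the two rates for a recording
share one denominator, and the choice is stated wherever rates appear.

**Potential vs actual false positives.**  Because the manual annotation
required an upper-half start and the automated scorer does not, many
first-pass false positives are genuine falls that merely began low.
The two-pass protocol scores at the working threshold (60 px), matches,
and then re-scores the same trajectory at 160 px: a drop starting below
the half-height line has less than half the vial to fall and cannot
reach 160 px, so the strict pass eliminates exactly that class.
First-pass unmatched predictions are *potential* false positives; those
that survive the strict re-scoring and remain unmatched are *actual*
false positives.

**Annotator screening.**  Inter-annotator reliability is measured by
Cohen's kappa, `κ = (p_o - p_e)/(1 - p_e)` with chance agreement from
the marginal label frequencies; recordings with κ < 0.75 are excluded
(exactly 0.75 is kept).  Kappa is implemented in-package because the
degenerate case — two identical constant label sequences, where the
formula is 0/0 — must resolve to 1.0 for screening to behave sensibly;
the implementation is cross-checked against an independent library
implementation on non-degenerate tables.

## Synthetic recordings

The generator produces seeded, bit-reproducible recordings that carry
their own ground truth, so every stage is testable without video
corpora.  Defaults mirror the assay: 30 fps, vial rows 50–375 (325 px
≙ 3 cm), fall displacements drawn from 200–320 px (all above the
160 px strict threshold and all starting in the upper half, so
programmed counts are recoverable at either threshold and under the
manual definition), descent dropout of 0.1–0.5 s, per-frame detector
miss rate 0.01 outside falls, and 0.5 px centroid jitter.

Between programmed falls the fly performs a reflected random walk on
the vial wall, pinned (Brownian-bridge style) to the next programmed
fall-start position so segment joins introduce no spurious jumps; mean
walking speed is 40 px/s (~3.7 mm/s), so per-frame steps are far below
the 60 px fall threshold.  Fall onsets are sampled uniformly subject to
a 3 s minimum separation — more than twice the maximum fall duration,
so events cannot interact — and a spec too dense to satisfy that is
rejected rather than silently adjusted.

Rendered video places a bright disk (intensity 220) for the fly on a
dark background (8) with a static glare band (90) below the stopper
position and, during each descent, a faint streak at intensity 20 —
12 above background, deliberately below the detector's threshold of 25,
so the rendered mechanism of dropout matches the real one.

What the generator does **not** emulate: fly morphology and posture
(wings, legs, righting attempts), walking-versus-standing onset,
multi-bounce descents, lighting drift, camera noise beyond Gaussian
centroid jitter, and any aging or dehydration physiology.  Passing
tests on synthetic data therefore demonstrate that the scoring and
evaluation machinery is correct given the gap-signature model of a
fall; they say nothing about detector robustness on real IR video,
which must be established against manually annotated recordings.  The
per-frame miss rate of a real detector outside falls is unknown; the
synthetic `dropout_rate` is a plausible free parameter, not a
calibrated one.

## Reference accounting table

The package ships the per-hour predicted/ground-truth fall accounting
for the reference test recording (a young male assayed in an empty
vial over 22 h, seven hours manually annotated; 253 predicted falls in
total).  The recomputation exercised by the tests and the acceptance
script is the *aggregation arithmetic* — column totals and rates —
because the underlying videos are not distributable; the per-hour
counts themselves are fixture inputs.

## Numerical choices and degenerate inputs

- Hour bins half-open; event hour = hour of start time; a movement pair
  belongs to the hour of its earlier member.
- Empty trajectory → no events (not an error); single detection →
  zero movement; empty event list → all-zero hourly counts.
- Matching with an empty prediction or truth list degrades gracefully
  (all of the other list unmatched); rates with zero predictions are 0.
- CSV floats are written with `repr` (shortest exact form) so
  write→read round-trips are exact and reruns are byte-identical.
- Output CSVs carry a header comment with the package version and a
  hash of the analysis parameters (output paths excluded), so reruns
  into different directories remain byte-comparable.

## Problem sizes

The test suite and acceptance script run on synthetic recordings of
10 s–10 min at 30 fps (up to 18 000 rendered 400×160 frames in the
closed video loop), 100 randomized trajectories for the criteria
oracle, and 50 random instances for the matching oracle — sizes chosen
to exercise every code path while keeping a full run in the low
minutes on one CPU.
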