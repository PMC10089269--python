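# Methods

This note records how `microskill` computes its quantities, the conventions
and defaults it fixes where the underlying metric definitions are open, and
what its synthetic test bed does and does not establish.

## Input model and conventions

The pipeline consumes per-frame instance segmentations of five
micro-neurosurgical instruments (Bipolar Forceps, Suction, Straight
Microscissors, Straight Needle Holder, Dural Tooth Forceps) plus an
optional boolean laser-dot channel.  Variant spellings of the instrument
names are normalised to these five labels on read.

Coordinates are 0-based pixel indices with the origin at the top-left,
x rightward and y downward.  Angles, however, follow the mathematical
convention — counter-clockwise from +x with the image y axis negated —
and live in [0°, 360°).  The default frame geometry is 640 × 480 at an
extracted rate of 12 frames/s, so the kinematic time step is
`dt = 1/12 s`.  All derived quantities are in pixel units; no attempt is
made to calibrate to millimetres, since monocular microscope video carries
no usable scale.

COCO-style JSON (polygon or uncompressed RLE segmentations) and 8-bit
label-PNG directories are the supported instance formats.  Polygons are
decoded with pixel-centre-inside semantics (a 10 × 10 axis-aligned square
yields exactly 100 pixels); RLE is the column-major uncompressed counts
list.  Compressed RLE strings are rejected with a clear error.  Laser
input may be a per-frame boolean CSV/JSON or per-frame detection-box
lists; one or more boxes in a frame counts as laser-on, since only
presence feeds the metrics.

## Tip and orientation from one mask

1. Soft masks are binarised at a configurable threshold (default 0.5).
2. The mask is thinned to a one-pixel-wide, connectivity-preserving
   skeleton.  Morphological thinning is the default; the exact
   medial-axis transform is available via `method="medial_axis"`.  The
   downstream contract (width, connectivity, endpoints) is what matters,
   and both satisfy it; thinning is roughly an order of magnitude faster
   on video-sized masks because the medial-axis routine rebuilds its
   lookup table per call.
3. Skeleton spurs shorter than 5 px (`spur_px`) are pruned before
   endpoint extraction: rasterisation grows whisker branches at blunt tool
   bases whose endpoints would otherwise compete with the true tip.  A
   branch is traced from each endpoint to its attachment pixel; the
   attachment pixel itself is removed only when a simple-point test shows
   its removal cannot break connectivity.  Simple paths are never pruned,
   so genuine tips are not eroded.
4. Endpoints are skeleton pixels with at most one foreground 8-neighbour
   (an isolated pixel is its own endpoint).  The tip is the endpoint
   nearest the image centre ((W−1)/2, (H−1)/2), ties broken by smaller y
   then smaller x.  Rationale: the operative field sits under the
   microscope centre and instruments enter from the frame border, so the
   distal working end is the centre-nearer one.  This choice also makes
   the tip rule consistent with the orientation anchor below.
5. The tip is then snapped to the mask pixel extremal along the tip-ward
   long-axis direction (ties broken toward the skeleton endpoint, then by
   (y, x)).  Thinning can stop a pixel or two short of a pointed apex;
   this refinement recovers the apex exactly on rendered templates.  It
   assumes a roughly straight instrument — a strongly curved tool would
   need the unrefined skeleton endpoint.
6. Orientation: the minimum-area rotated rectangle of the mask (rotating
   calipers over the convex hull, via shapely) is reduced to its long-axis
   midline; the midline endpoint closer to the image centre anchors a ray
   through the other endpoint, and the ray's angle is the orientation.
   Masks with fewer than 3 pixels have no orientation and use their
   centroid as tip; collinear masks fall back to the line through their
   extreme pixels with the same anchoring.

The centre-anchored convention means a tool whose scripted pointing
direction is θ reports θ + 180° when its tip is the centre-nearer end; the
synthetic ground truth stores orientations in the estimator's convention
so recovery can be asserted directly.  The anchor flips by 180° if tip and
base become equidistant from the centre mid-track; the scripted cohorts
keep tips pointed toward the centre so this cannot happen, and on real
data such flips would inflate the angular metric — a known limitation.

## Temporal cleaning and linking

Frame-wise segmentation of video flickers.  The cleaning filter operates
on each class's boolean presence series with two parameters: interior
off-runs shorter than `min_off_frames` are filled first, then on-runs
shorter than `min_on_frames` are deleted (the order is fixed and the
operation is idempotent).  Defaults are 3 and 3 frames — 0.25 s at 12 fps —
chosen to remove the 1–3-frame spurious detections and dropouts typical of
per-frame models while never inventing presence farther than
`min_off_frames` from an observed detection.  This two-parameter
run-length filter is this package's own, deliberately simple, temporal
post-processing stage; it is not a re-implementation of any published
video-detection post-processor.

Detections are gated by the smoothed presence of their class and linked
into per-tool tracks greedily: per frame and class, open tracks (last
sample at most `max_gap_frames = 3` frames old) and detections are matched
by minimum-total-distance assignment, rejecting pairs farther than
`max_jump_px = 60` px (≈ a tool-length jump per frame); unmatched
detections open new tracks.  The result is invariant to detection order
within a frame.  Gap frames contribute no samples, and kinematic
differencing never spans a gap.

For the idle/bimanual counts, a frame's effective tool count is the number
of gated detections per class, raised to 1 where smoothing bridges a
dropout: a tool the filter declares present is not "idle" merely because
one frame's mask is missing.

## Kinematic and handling summaries

Speeds are first differences of tip position divided by `dt`; acceleration
and jerk are successive differences of the speed series.  Each gap-free
segment of a track contributes independently, and segments too short for a
derivative order contribute nothing; a summary field whose series is empty
is reported as undefined (`None`), never silently zero.

Means of acceleration and jerk use magnitudes by default.  The signed
means telescope — the signed mean acceleration of any segment is just
`(v_N − v_1)/((N−1) dt)` — so they measure only net speed change, not
movement smoothness; magnitudes are the standard smoothness convention,
and a `signed` switch restores the literal signed sums for comparison.
Standard deviations use population normalisation (divide by N).  A test
asserts the magnitude convention differs from the telescoped value on
non-monotone speed profiles, guarding against an accidental signed
implementation.

The angular accumulation wraps each orientation step into (−180°, 180°]
and sums magnitudes divided by `dt`, normalised by path length; it is
undefined when the path length is zero.  Per-recording summaries pool the
derivative samples of all tracks, sum their path lengths, and normalise
the pooled angular accumulation by the pooled path length.  Because raw
path length scales with segment duration, the per-second rate
`path_length_per_s` is reported alongside it.

Idle fraction counts frames with no tool, bimanual fraction frames with
two or more; the conditions are disjoint, so their sum never exceeds 1
(asserted).  The inter-tip distance averages, over frames with at least
two detections, the distance between the two highest-scoring tips.

## Microscope adjustments

The laser channel is smoothed with the same run-length filter; each
maximal on-run is one adjustment event.  This equates one continuous
activation of the focusing aid with one repositioning action — the aid
stays lit throughout a single adjustment.  Metrics are computed over a
configurable window (default 3000 s, the first 50 minutes, where early-case
workload is comparable across recordings): the count of events with onset
inside the window, and the maximum and median of consecutive onset-to-onset
intervals in seconds.  With fewer than two in-window events the intervals
are undefined, not zero.  The even-length median is the mean of the middle
two intervals.

## Statistics

The two-sample Mann-Whitney U test uses pooled midranks;
`U_a = R_a − n_a(n_a+1)/2` and the reported statistic is `min(U_a, U_b)`.
The exact two-sided p-value is `P(min(U_A, U_B) ≤ U_obs)` computed by
dynamic programming over all `C(n, n_a)` subset assignments of the
observed midrank multiset — valid under ties, unlike the textbook
no-ties tables.  For pooled n > 25 a tie-corrected normal approximation
with continuity correction (on by default) is used instead, and requesting
the exact method there downgrades with a warning.  Exact for small
cohorts is the default because published small-sample p-values in this
area are sometimes below the exact floor (2/252 ≈ 0.0079 for 5 vs 5),
betraying an approximation; recording the method used in every output row
avoids that ambiguity.  No multiple-testing correction is applied: the
metrics are reported descriptively, one test per metric.

Box-plot summaries use midpoint-interpolated quartiles, whiskers at the
most extreme observations within 1.5 IQR of the quartiles, and flag
everything beyond as outliers.

## The synthetic test bed

The generator renders tapered isosceles polygon silhouettes — pointed tip,
widening over a configurable taper fraction to full width — moved along
linear, circular, polyline or stationary trajectories at 640 × 480 / 12 fps,
with per-tool visibility windows, optional i.i.d. Gaussian per-frame
tremor (real motion, reflected in the ground truth), and a scripted laser
schedule.  All randomness flows from one seeded generator per scene;
identical specs and seeds are bit-identical.  A corruption pass injects
i.i.d. false negatives, 1–3-frame false positives of random class, rigid
tip jitter and score noise, emulating the failure modes of frame-wise
detectors.

Scripted "expert" and "novice" cohort scenes realise the qualitative
contrasts expected of experienced versus novice operators: the expert
moves slowly and smoothly (circular needle-holder motion at 18–33 px/s
with steady rotation, no tremor, both tools near the centre, minimal idle
time) while the novice moves fast with 2–2.5 px tremor, fixed orientation,
long idle windows and widely separated tools; expert laser schedules fire
every 50–90 s, novice every 150–300 s.  Cohort runs use 15 s scenes at
n = 8 recordings per group — long enough that every metric's direction
separates decisively, small enough that a full three-seed cohort
comparison runs in about a minute on one CPU.

What passing these tests shows: the geometry, filtering, kinematics and
statistics are implemented to specification and recover analytically known
quantities.  What they do not show: robustness to real surgical imagery —
deformable and specular instruments, occlusion by tissue or hands,
segmentation masks with holes or fragments, camera motion, curved tools,
or class confusion between visually similar instruments.  Tip and
orientation accuracy on rendered polygons (≤ 3 px, ≤ 3°) is an upper bound
on what real masks would give.

## Numerical choices and edge cases

- Rendered masks stamp the rounded tip pixel so a pointed apex never falls
  between pixel centres; rasterisation tolerance on recovery assertions is
  3 px / 3°.
- Undefined metrics propagate as `None`/NaN and are dropped pairwise in
  group comparisons; a metric undefined in an entire group yields a
  comparison row with an undefined p.
- Empty recordings analyse cleanly: idle fraction 1.0, every motion metric
  undefined, exit code 0 with a warning.
- Every output directory carries a manifest naming the configuration hash,
  package version, stage counts (instances before/after filtering, track
  count) and the per-class presence series before and after smoothing, so
  before/after presence plots can be regenerated from any run.  Inputs are
  recorded by file name and content hash, keeping identical runs
  byte-identical wherever they are executed.
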