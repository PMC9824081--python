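# Methods

## Problem setting

The package targets tracking-by-detection on fixed-camera herd footage:
an external detector emits per-frame bounding boxes (with confidences
and optionally instance-mask areas), and the tracker's only job is to
associate boxes across frames into persistent identities.  Two trackers
with different modelling assumptions are provided, together with the
evaluation machinery to compare them and a simulator that generates the
study conditions when real footage is unavailable.

## Lightweight geometry tracker

### Cost model

A track keeps a bounded history of its past boxes.  The matching cost
of extending a track with a candidate detection appends the candidate
as a tentative current-frame entry and averages, over the last `N`
consecutive steps (default `N = 5`),

* the Euclidean centroid displacement per step (`Ldist`, pixels), and
* the absolute aspect-ratio change per step (`Ardist`, where
  `Ar = w/h`).

The two terms are summed raw, `COST = Ldist + Ardist`, mixing pixel and
dimensionless units.  This is deliberate: at the working image scale
(boxes ~180 × 110 px, speeds of a few px/frame) the location term
dominates and the aspect term acts as a posture-change tiebreaker.
Optional weights `(w_L, w_Ar, w_mask)` allow normalisation; the third
term, a mean absolute mask-area step, is computed but carries weight 0
by default — area differences are already partially captured by the
aspect term, and mask areas are not always available.

The window semantics: the sum runs over the last `N` consecutive-entry
steps ending at the candidate, divided by the number of steps actually
available when the history is shorter.  History entries are treated as
consecutive regardless of frame gaps (a reappearing animal's jump is
one "step"); this keeps the cost meaningful for re-matching after
occlusion without introducing a motion model.

### Matching, re-matching, lifecycle

Per frame, the active-track × detection cost matrix is solved by the
Hungarian algorithm under two gates: `COST ≤ cost_gate` and
`IoU ≥ iou_gate` (default 0, i.e. cost-driven only).  Infeasible pairs
can never match; the solver maximises matched pairs first, then
minimises total cost (big-M reduction).  A greedy nearest-cost variant
is available behind a flag for ablation.

`cost_gate` defaults to 15.  Because the cost averages the candidate
jump over `N = 5` steps, a gate of 15 admits single-step displacements
up to roughly 60 px — generous for walking speeds of ≤ 6 px/frame plus
jitter — while rejecting the ≥ 80 px jumps that would capture a
neighbouring animal's detection when the animal's own box is missed.
This calibration matters: with a loose gate, the maximise-cardinality
objective aggressively rematches bereft tracks to other animals'
detections, scrambling identities.

Unmatched tracks become *lost* (never matched directly again).
Unmatched detections receive provisional fresh IDs immediately, so no
detection is ever unlabelled.  Every `rematch_period` frames (default
30, i.e. every 1.2 s at 25 fps), identities created since the previous
boundary are re-matched — at their first-appearance box, which is where
they extend a lost trajectory — against lost tracks not older than
`max_lost_age` (default 1500 frames), with the same gated Hungarian
procedure plus the constraint that a re-appearance must begin after the
disappearance.  A success rewrites the provisional records to the old
ID in the in-memory buffer and reactivates the lost track; a failure
leaves the fresh ID permanent.  Lost tracks strictly older than
`max_lost_age` are deleted; IDs are never reused.  Re-matching never
steals an ID from an active track.

## Kalman + appearance tracker

The comparison tracker follows the Deep-SORT family design.  The state
is 8-dimensional — box centre, aspect ratio, height and their
per-frame velocities — under a constant-velocity transition; process
and measurement noise scale with box height (scale weights 1/20
position, 1/160 velocity).  Association is two gated Hungarian stages
per frame: confirmed tracks by appearance (minimum cosine distance
between the detection's embedding and the track's gallery, gate
`max_dist = 0.9`), then everything remaining by IoU distance of the
predicted box (gate `max_iou_distance = 0.8`).  A time-since-update
matching cascade is intentionally omitted — plain global assignment per
stage.  Lifecycle: confirmation after `n_init = 1` association (a
track is trusted immediately, appropriate when the detector has very
low false-positive rates), deletion of tentative tracks on their first
miss, and deletion of any track unseen for more than `max_age = 1500`
frames (one minute at 25 fps — long enough to bridge extended
occlusions in a closed arena).  Each track's appearance gallery is a
FIFO of at most `nn_budget = 100` embeddings.

The appearance gate of 0.9 is permissive for cosine distances (0 =
identical, 1 = orthogonal); it is kept as the working default for herd
footage where coat appearance is weakly discriminative, but it deserves
scrutiny when porting to other settings.

## Appearance stage

The learned embedder this tracker would use in production is described,
not trained: `build_reid_architecture()` returns the 10-layer CNN
descriptor (two 3×3 convolutions at 32 channels, max-pool, four
residual blocks rising to 128 channels at 16 × 16, a 128-wide dense
layer, batch-norm and ReLU), with training metadata (Adam, learning
rate 1e-5, batch 128, 100 epochs) attached for anyone wiring a
deep-learning backend.  The descriptor validates shape chaining — each
layer's input is the previous output, spatial sizes never grow, and
element-wise layers preserve width.  Note the printed patch/stride
column is not arithmetically consistent with the output sizes in two
rows (a stride-1 block halving the spatial size, a stride-2 block
keeping it); the descriptor reproduces the published table as-is and
the validator deliberately does not check stride arithmetic.

For everything runnable at desk scale the package ships a handcrafted
embedder with the identical interface contract: crops resized to
128 × 128 (nearest-neighbour, deterministic), tiled 4 × 4, an 8-bin
intensity histogram per tile, L2-normalised to a 128-dim unit vector.
It is deterministic and has no photometric invariance — affine
intensity changes move the vector.  It separates identities exactly
insofar as their intensity statistics differ, which is the regime the
synthetic renderer produces (per-identity coat tone and stripe
texture); on real uniformly-coloured livestock a learned embedder is
required for comparable benefit.

Unsupervised identity splitting for building a re-ID dataset is greedy
medoid agglomeration: crops visited in (frame, detection) order join
the group with the highest mean-embedding cosine similarity if it
reaches the threshold, else found a new group; an optional spatial
continuity gate (`max_jump`) restricts joining a group seen within
`frame_gap` frames to crops that have not teleported.  Threshold 0
collapses everything to one group (non-negative features), threshold
above 1 yields singletons.  Dataset export writes one folder per
identity and assigns train/test by a deterministic hash of the relative
path (≈ 80/20), so re-export is idempotent.

## Evaluation metrics

Detection: per-frame Hungarian matching maximising total IoU among
pairs at or above the IoU threshold (default 0.5); precision
`TP/(TP+FP)`, recall `TP/(TP+FN)`, `F1 = 2TP/(2TP+FP+FN)`.  Average
precision uses a confidence-descending sweep with per-frame greedy
ground-truth claiming and the all-points interpolated area under the
precision–recall curve; multi-threshold mAP averages over the COCO grid
0.50:0.05:0.95 (10 thresholds).

Tracking follows the CLEAR convention.  Per frame, ground-truth ↔
prediction pairs matched in the previous frame are kept while they
still meet the IoU gate (persistence prevents spurious switch counting
when two matchings tie); the remainder is matched by Hungarian on IoU.
An identity switch is counted when a ground-truth identity's matched
predicted ID differs from the predicted ID it last matched, across
gaps.  A fragmentation is a tracked → untracked transition later
followed by tracked again.  Then

```
MOTA = 1 − (ΣFN + ΣFP + ΣIDSW) / ΣGT
```

MOTA is at most 1 and can be negative.  The raw error ratio is also
exposed.  Undefined ratios (no ground truth, no predictions) raise an
`UndefinedMetricError` rather than silently returning 0, because silent
zeros corrupt aggregate tables.

Proximity contacts — the input to social-behaviour analysis — are
frames where two identities' box centroids are closer than a distance
threshold, merged into maximal consecutive intervals and filtered by a
minimum duration (default 25 frames = 1 s).

## Herd simulator

The simulator generates the conditions the trackers must survive:
10–25 long-lived targets in a fixed 2560 × 2048 px arena at a notional
25 fps.  Motion is waypoint-seeking — each animal walks at an
individual speed (mean 4 px/frame) towards a random waypoint with
Gaussian heading noise (sd 0.15 rad), re-targets on arrival or
spontaneously (rate 0.002/frame, producing abrupt turns) — with soft
pairwise repulsion keeping body centres at least ~45 % of a body width
apart, since solid animals do not interpenetrate; boxes are clamped to
the arena.  Posture flips (standing ↔ lying, rate 0.005/frame) switch
the body box between aspect ratios of about 1.6 and 3.1, exercising the
aspect-ratio cost term.

Detector corruption: independent per-box misses (default 5 %),
Gaussian centroid/size jitter (sd 2 px), union-box merging of box
groups whose pairwise IoU reaches 0.6 (mutual occlusion; the merged
detection carries the union area as its mask area), and
Poisson-distributed clutter (0.2 boxes/frame).  Confidences are uniform
on [0.5, 1]: real detectors emit near-1 confidences and only ranking
matters to the metrics.  All randomness derives from the single
scenario seed; equal configurations are bit-identical.

The renderer draws per-identity-textured dark ellipses (tone, speckle
and stripe parameters drawn once per identity) on a noise-textured
ground, either full frames or single windows, so detection crops can be
produced cheaply for the appearance stage.  What the simulator does
*not* model: fisheye distortion, illumination cycles, shadows,
photorealistic coats, or correlated detector failures.  Passing tests
on synthetic herds therefore demonstrate algorithmic correctness of
association, re-matching and metrics — not detector robustness or
learned-embedder quality on real footage.

## Numerical and design choices

* Boxes are continuous `(left, top, width, height)` pixels, origin
  top-left (MOT-Challenge convention); frames and IDs are 1-based on
  disk.  Degenerate boxes (non-positive size) are rejected at
  construction.
* IoU is clamped to [0, 1] against floating-point roundoff at box
  edges.
* Assignment ties resolve deterministically (scipy's solver on a fixed
  matrix); the tracker contains no randomness, so identical inputs give
  bit-identical outputs.
* The lightweight tracker's fast cost-matrix path computes the windowed
  distances incrementally per track; it is property-tested to equal the
  reference per-pair cost function.
* Histories are capacity-bounded (64 entries) so memory is O(tracks),
  not O(frames).
* The prune boundary is strict: a lost track aged exactly
  `max_lost_age` is kept, one frame more deletes it.  Likewise
  `MAX_AGE` in the Kalman tracker.
* Problem sizes in the test suite and acceptance script (herds of
  10–25 animals, 200–1500 frames, 100-scenario metric sweeps) were
  chosen to exercise every code path at desk scale while keeping a full
  run in the tens of seconds.

## Known limitations

* The lightweight tracker has no motion extrapolation: a long occlusion
  of a *moving* animal exceeds the cost gate at re-match time and the
  identity is honestly lost (a fresh ID persists).  The Kalman tracker
  bridges such gaps better but depends on the appearance stage when
  targets reverse direction while occluded.
* `tracked_count` counts persistent clutter tracks as tracked
  identities when clutter survives the minimum-length filter.
* The handcrafted embedder is a deterministic stand-in with documented
  limits (see above); conclusions about appearance-based re-ID on real
  animals require the learned backend.
* The identity-splitting threshold is a free parameter; the package
  provides no automatic threshold selection.
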