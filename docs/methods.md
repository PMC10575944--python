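# Methods

## Problem setting and model

`herdtrack` is a tracking-by-detection system: an upstream instance
segmenter provides per-frame masks and boxes, and the tracker's job is
purely data association and identity lifecycle. Two modeling assumptions
shape everything else:

1. **Low frame rate, slow targets.** At the 1 fps working rate cattle move
   far relative to their body size but stay within a bounded radius, so a
   fixed motion gate (*r* = 350 px at the native resolution) replaces a
   motion model. There is deliberately no Kalman-style prediction:
   detections are associated directly against last-seen positions.
2. **Weak color identity.** Herd coats cluster in dark browns and blacks,
   so no single cue suffices. Four cues are fused: location, color
   moments, co-occurrence texture, and a learned appearance posterior.

## Descriptors

**Color moments.** Per channel, the population mean, standard deviation
and skewness of the mask pixels (9 numbers), in CIELab by default (the a/b
channels are shifted by +128 so the vector is non-negative). Skewness of a
constant channel is defined as 0. Regions are compared by cosine distance
on the 9-vector, which factors out overall brightness scaling.

**Co-occurrence texture.** Channels (YCbCr by default) are uniformly
quantized to L = 8 levels over the half-open range [0, 256). L is a
configuration choice: 8 keeps an 8×8 pair matrix well populated on
animal-sized regions (a few thousand pixels). For each channel and each
orientation θ ∈ {0°, 45°, 90°, 135°} at offset distance s = 1, pair counts
are accumulated **only when both pixels lie inside the mask**, so
background never leaks into the descriptor. Counting is symmetric by
default (both directions accumulated before normalizing), which makes 0°
and 180° equivalent and is consistent with using only four angles. The
four summary statistics use the standard probability-weighted forms;
correlation is reported as 0 with a degenerate flag when a marginal
variance vanishes (e.g. constant regions). Thin masks that admit no pair
at some angle simply drop that angle; if a channel has no valid angle at
all its texture distance is treated as missing and excluded from fusion.

**Rotation-invariant texture distance.** Animals rotate freely under an
overhead camera, so per channel and per statistic the distance is the
minimum absolute difference over all 16 orientation pairs — stricter than
comparing matched angles only, and exactly zero for a 90°-rotated copy of
the same region (verified by a property test at 1e-9).

**Appearance embedding and posterior.** The embedding backend is
pluggable behind one interface. The default is a deterministic
hand-crafted embedder (48 histogram + 16 co-occurrence dimensions over the
mask pixels); a pretrained CNN backend can be registered at run time where
a deep-learning stack is available. Embeddings of confidently matched
crops (fused cost ≤ `buffer_admit_max_cost`, default 0.5) are buffered per
track (FIFO, capacity 200) — the admission margin exists so that one bad
association cannot poison the training labels. Once every active track
has `min_per_class` = 30 crops, a one-against-one RBF SVM with sigmoid
(Platt-style) calibration is trained on the full buffers and retrained
every 30 frames; non-shuffled stratified folds and a fixed seed keep
training deterministic. The posterior used for a candidate pair (p, q) is
the posterior of *p's own class* given q's embedding — each pair gets its
own P_dist = 1/P (clamped at P = 1e-6). Before the first training the
posterior cue is flagged unavailable and the tracker runs on the other
three cues.

## Association

All gated pairs of a frame are stacked into a 15-column matrix
(L, C, 12 texture components, P). Each column is min–max normalized over
the frame's gated pairs (a constant column, including the single-pair
case, maps to zero); normalization is per frame because the raw cue scales
drift with scene content, and the alternative (running statistics) is
available behind configuration. For fusion the texture block is collapsed
to its mean first so texture does not dominate dimensionally; the fused
cost is a weighted mean (default weights ¼ each, renormalized over
available cues). The frame matching is the minimum-total-cost one-to-one
assignment over gated pairs (Hungarian; a greedy nearest-first matcher is
provided for ablation). Ties are broken toward smaller location distance,
then lower track index, via an infinitesimal perturbation, which also
makes the matching deterministic.

**Forced-match guard.** A match whose fused cost exceeds `max_cost`
(default 0.8) is sent to unmatched rather than forced. This guard is only
meaningful when the pair actually competed for alternatives: per-frame
min–max normalization is scale-free, so when *every* gated pair is a
correct match, some correct pair necessarily normalizes to ≈ 1 and a flat
threshold would misfire (observed as tracks flapping between missing and
temporary). A pair whose track and detection have no other gated
candidate is therefore exempted from `max_cost` and instead checked
against raw-appearance sanity bounds: it is rejected only when **both**
its raw color and raw texture distances exceed typical cross-animal
levels (0.003 and 0.02, the between-animal medians on calibration
scenes).

## Lifecycle

Unmatched tracks move to a missing-object database that freezes their
last descriptors and centroid (records expire after
`max_missing_frames` = 600 frames). Unmatched detections are first offered
to existing temporary tracks (same gating and fusion, second pass), then
spawn new temporary tracks. A temporary track is resolved on a fixed
schedule:

* at `born + Age_temp/2` (15 frames): if seen fewer than `Age_temp/2`
  cumulative frames → **noise**, deleted together with its buffered crops.
  Cumulative (not consecutive) counting is used, so a flickering detector
  does not spuriously kill a real animal.
* at `born + Age_temp` (30 frames): its probation-averaged appearance is
  compared against every missing record. A record qualifies when the
  averaged color distance < `th_color`, the averaged texture distance
  (collapsed to its scalar mean, since a single threshold implies a
  scalar) < `th_texture`, the averaged inverse posterior < `th_posterior`,
  and the record-to-birth location distance ≤ `r_missing` (default 2r =
  700 px — generous, because missing animals keep moving). The
  best-scoring qualifying record resumes its id (**missed**); otherwise
  the next unused id is assigned (**new**). The posterior term is skipped
  when no classifier is trained yet or the record's class is not in the
  model (an animal can vanish before the bootstrap) — the color and
  texture gates then decide alone.

A resumed track keeps its original classifier class. Permanent-id output
is emitted only for active tracks seen in the current frame, so an object
under probation contributes false negatives for at most 30 frames but can
never contribute a false positive — the design accepts bounded FN cost to
drive FP to zero.

## Threshold calibration

The probation thresholds compare raw (unnormalized) distances and are not
universal constants; they depend on detector, resolution and coat
statistics. The shipped `calibrate-thresholds` procedure measures, on
generated calibration scenes (one mixed-coat, one look-alike), the
distribution of each distance *within* an animal over time (snapshot vs. a
later 20-frame average — the same shape as the missed-vs-probation
comparison) and *between* animals, then places each threshold at the
geometric mean of the within-95th percentile and the between **median**.
The median (not minimum) is deliberate: individual pairs may legitimately
coincide on one cue (look-alike coats have near-zero color distance), and
the missed decision requires every gate to pass, so each threshold only
needs to sit above self-variation and below the *typical* cross-animal
distance. The shipped defaults from this procedure at seed 0 are
`th_color` = 4.5e-5, `th_texture` = 0.011, `th_posterior` = 17.0.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `r_px` | 350 px | association gate radius (resolution-specific) |
| `age_temp_frames` | 30 | probation length; noise check at half |
| `min_per_class` | 30 crops | classifier bootstrap requirement |
| `retrain_interval_frames` | 30 | classifier refresh (30 s at 1 fps) |
| `r_missing` | 700 px | reachability gate for resuming a missing id |
| `max_cost` | 0.8 | fused-cost rejection under competition |
| `cm_levels` | 8 | co-occurrence quantization depth |
| `max_missing_frames` | 600 | missing-record expiry |

## Synthetic scenes

The generator emulates what matters to the tracker, not photorealism:
dark, low-saturation elliptical objects on a lighter floor; coats drawn
from structurally different two-tone pattern families (speckle, fine and
coarse stripes, checker, spots) whose tones target distinct quantization
bins, anchored in object-local coordinates so patterns travel rigidly with
the object; smooth momentum random walks confined to loosely separated
pen regions (512×512 scenes, 1–8 objects, step σ = 6 px/frame); scripted
full occlusions (object or static pole), entries/exits; and a corruption
pass (misses, mask jitter, merges, short-lived static noise blobs). Scene
generation asserts that object textures are pairwise separable, and every
fixture regenerates deterministically from (scenario, seed) — nothing is
stored on disk.

What the generator does **not** model, and what passing tests therefore do
not demonstrate about farm video: non-rigid body deformation, lighting
changes, partial occlusions with mask truncation, detector box drift
correlated with pose, fisheye distortion, and appearance change across an
occlusion. The look-alike scenario (identical base color, different
pattern) is the targeted stress test for the texture cue; real herds are
harder.

Scenario sizes (100–140 frames, 2–5 objects) were chosen so the full
suite and the acceptance script each run comfortably on a single CPU
while still containing every lifecycle transition several times over.

## Numerical and degenerate-input choices

* Quantization bins are half-open with the top value clipped into the last
  bin; channel ranges are fixed at [0, 256) after non-negative shifts.
* Cosine distance on a zero-norm moment vector raises (cannot occur for
  real image regions; guarded anyway).
* Empty masks are rejected at ingestion with a warning, never silently
  tracked.
* The assignment perturbation (1e-9 · normalized L_dist + 1e-12 · row
  index) is orders of magnitude below any meaningful cost difference.
* All randomness (scene generation, classifier folds) flows from explicit
  seeds; reruns are byte-identical.

## Known limitations

* Identity recovery relies on appearance stability across the occlusion;
  an animal that reappears looking different (lighting, mud) will be
  declared new. Thresholds would need recalibration per installation.
* Probation hides real animals for 30 frames (30 s), a deliberate
  FN-for-FP trade.
* Per-frame min–max normalization makes fused costs incomparable across
  frames; all absolute decisions therefore operate on raw distances.
* The evaluation module implements MOTA/MT/PT/ML/Frag only; MOTP is
  intentionally omitted because detector boxes are taken as the true
  locations, and newer families (IDF1, HOTA) are out of scope.
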