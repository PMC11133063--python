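# Methods

## Problem setting

A mobile eye tracker yields a head-centered gaze signal (here 120 Hz) and a
scene-camera video (here 30 fps, 320×240, pinhole intrinsics).  Each gaze
sample is to be classified as gaze fixation (1), gaze pursuit (2), gaze
shift (3) or gaze following (4).  The central difficulty is that the eye
signal lives in a head-centered frame while the events are defined in a
world-centered frame; head and body motion must therefore be recovered
from the scene video itself.

Preprocessing removes unlabeled samples (label 0), blinks (label 5) and
user-supplied calibration windows.  Every removed block sets a
`cut_before` flag on the next retained sample; the flag is honored by all
difference-based features, by interpolation and by event segmentation, so
no computation ever straddles a removed span.

## Features

Per-sample feature vector, in fixed order: eye velocity, eye direction,
head rotation velocity, head rotation direction, body translation
velocity, gaze-patch similarity.

**Eye kinematics** are computed from consecutive sample pairs only (window
of two).  Velocity is the great-circle angle between the two unit gaze
vectors per unit time, computed in the numerically robust
`atan2(|g_i×g_j|, g_i·g_j)` form (angular, not image-plane, velocity — the
head-centered signal is a direction, and angular velocity is invariant to
the camera projection).  Direction is `atan2(Δelevation, Δazimuth)` mapped
to [0°, 360°), with 0° rightward and 90° upward; zero-motion pairs get
direction 0 so the matrix stays dense.  Pair features live at pair-midpoint
times (the symmetric choice) and are interpolated back to sample times.

**Camera motion.**  Each consecutive frame pair is processed by a
classical monocular odometry backend:

1. grayscale conversion and 2× block-mean downscaling; up to 150
   Shi-Tomasi corners;
2. SSD block matching (11×11 blocks, ±8 px search, global
   phase-correlation pre-shift) with sub-pixel parabola refinement,
   followed by a second ±2 px refinement pass at full resolution
   (~0.05 px accuracy — integer-located multi-scale keypoints are far too
   coarse for recovering rotations of a fraction of a degree);
3. robust pose: RANSAC homography over the matches (threshold 1 px).  If
   it explains ≥ 60% of matches the scene-pair is planar-dominant or
   rotation-only and the calibrated homography is decomposed by the SVD
   method into rotation + plane normal + translation direction, with a
   pure-rotation special case when the singular values are equal (tolerance
   1e-3) and a fronto-parallel prior to break the planar two-fold
   ambiguity.  Otherwise a RANSAC essential matrix is estimated on
   normalized coordinates and decomposed with the cheirality check.  The
   homography-first design is deliberate: the 8-point essential estimate is
   degenerate both for (near-)coplanar scene points and for (near-)zero
   translation, which are exactly the common cases for a scene camera
   looking at walls/tables while the head rotates.  Frame pairs with a
   median displacement under 0.2 px short-circuit to the identity pose.

The pose is reported as a unit quaternion canonicalized to `w ≥ 0`, mapping
frame k−1 coordinates to frame k (`x_b = R x_a + t`).  Head-rotation
velocity is the quaternion rotation angle over the frame interval;
direction is `atan2(tilt, pan)` with pan positive rightward and tilt
positive upward (roll ignored).  Because monocular geometry cannot observe
metric translation, body translation velocity is a **derotated parallax
proxy**: the median matched-point displacement remaining after the
rotational flow predicted by the recovered rotation and the intrinsics is
removed, in px/s.  It is ≈ 0 for a stationary or purely rotating head and
grows monotonically with walking speed — the discriminative property the
classifier needs — but its units are not commensurable with a
learned-depth odometry's metric output, so models must be retrained per
camera geometry.  Failed pairs (too few inliers, degenerate geometry) are
marked invalid and bridged by interpolation rather than zero-filled, which
would fabricate "stationary head" evidence.  External odometry output can
be injected through a pose CSV, bypassing the backend.

**Patch similarity.**  A 64×64 px grayscale patch is extracted around the
gaze point nearest in time to each frame; consecutive patches are scored
with zero-normalized cross-correlation (range [−1, 1], invariant to affine
intensity changes).  Patches with less than half their area inside the
frame are invalid (zero-filled outside); zero-variance patches score 0.
ZNCC plays the role of a learned two-patch similarity network here: what
the pipeline needs is only *high within-object, low across-object*
similarity, and any backend honoring the two-patch score contract can be
plugged in (each documents its own range).

**Interpolation.**  Every channel is brought to the gaze timestamps with a
not-a-knot cubic spline through its valid knots (linear for 2–3 knots);
invalid knots are dropped before fitting, which is how odometry/patch gaps
are bridged.  Queries outside the knot span are clamped to the boundary
value — cubic extrapolation blows up at recording edges, and clamping keeps
label alignment instead of dropping rows.  Angular channels are unwrapped
(period 360°) before fitting and re-wrapped after; naive interpolation is
wrong at the seam (350° and 10° must average to 0°, not 180°).  Eye
channels are fitted per contiguous segment so cuts are never bridged.
Non-negative channels are clamped at 0 and ZNCC at [−1, 1] after
interpolation (spline undershoot).

## Balancing, splitting, classification

The **within-event random sample extractor** removes or subsets samples at
a per-class ratio (quota / pooled class count) applied consistently across
recordings, with largest-remainder rounding so pooled totals hit quotas
exactly.  Only event-interior samples are eligible; the first sample of
every event is never extracted, and boundary (segment-last) samples are
drawn only when a quota is otherwise infeasible (logged relaxation).  Every
event therefore survives with its order intact.  One seeded generator
drives all randomness.

*Leave-one-out*: each recording is held out in turn; the pooled remainder
is undersampled to the rarest class (removal mode) and trains the forest;
the held-out recording is scored **unbalanced**.  TP/FP/FN counts are
pooled across folds before computing final scores (robust to folds where a
class is absent).  *Train-test split*: class counts are first equalized by
deleting samples from the *beginning* of each recording — every deletion
boundary sets a cut flag so same-class events cannot merge — then 20% of
each class is extracted within events as the test sequence (original order
preserved) and the remaining 80% trains one model.

The decision unit is a random forest over the six features, sample-wise
(temporal context lives in the features).  Hyperparameters are pinned
(100 trees, Gini, unlimited depth, √p features, bootstrap — the scikit-learn
1.x defaults at pin time) and stored in the model artifact together with
the seed, class set and feature order, so "defaults" survive library
upgrades.  Class scores are the fraction of trees voting per class.

## Scoring

One-vs-all per class: precision `TP/(TP+FP)`, recall `TP/(TP+FN)` (0 on
zero denominators, flagged), `F1 = TP/(TP+(FP+FN)/2)` ≡ `2PR/(P+R)`.
Sample-level scores compare timestamps; event-level scores match each
ground-truth event (maximal same-label run, split additionally at cut
flags) to the most frequent predicted class in its span — majority voting;
ties go to the tied class occurring earliest in the span (deterministic).
Weighted averages use relative class frequencies in the test set (sample
frequencies at the sample level, event frequencies at the event level).
Event-level scoring is *generally* more lenient than sample-level but not
provably so; no such inequality is asserted.  A label-merge option (e.g.
4→1, folding following into fixation) is applied before training for
three-class comparisons.

## Synthetic recordings

The simulator emulates the structure of annotated natural-viewing
datasets: 120 Hz gaze with labels 0–5 (blink/unlabeled injection optional,
default off), 30 fps 320×240 scene video, pinhole intrinsics
fx = fy = 277 px (≈ 60° horizontal field).  The world is a textured plane
10 units ahead (multi-scale noise, 160 px cells with distinct
contrast/smoothness statistics, fine detail everywhere so corners are
always detectable) plus textured square objects at 6 units giving
foreground parallax; rendering is homography-exact for the background, so
the scripted camera trajectory is a usable oracle for the odometry.

Default event kinematics, chosen once as representative of natural
viewing: fixations/followings/pursuits of 1.5–2.2 s in a repeating cycle
with a gaze shift between each; GFo pans at 10–16 deg/s with lateral body
translation 0.3–0.8 units/s (steered back toward center when a pan would
leave the texture); GP objects sweep at 5–12 deg/s; GS durations 35–70 ms
with minimum-jerk profiles whose peak velocity lands in the 200–500 deg/s
band (peak = 1.875 × amplitude / duration).  Gaze jitter is Gaussian with
0.1° SD, smoothed over ~3 samples: white noise at 120 Hz would alias into
tens of deg/s of spurious sample-to-sample velocity, which no real
fixation signal shows.  Event transitions are continuous in gaze position
(each saccade lands on the next event's target).

What the simulator does **not** model: lighting changes, motion blur,
rolling shutter, lens distortion, occlusions, eyelid/pupil physics,
tracker-specific noise spectra, camera roll, or depth-varying clutter.
Passing tests therefore demonstrate the pipeline's mechanics and
geometry — not field performance on real recordings, which depends on
retraining per device and dataset.

## Problem sizes and numerical choices

The test suite validates the classifier end-to-end on six simulated
60-second recordings (≈ 43k samples) under leave-one-out; the
reproduction script uses six 20-second recordings as its study size, with
odometry probes on 30-frame clips.  RANSAC uses a fixed internal seed, so
pose estimation is deterministic; all other randomness flows from
user-supplied seeds (fold seeds are spawned from one `SeedSequence`).
Degenerate inputs have defined behavior throughout: identical frames →
identity pose; constant patches → score 0; single-sample segments → no
pair features (logged); segments without knots → nearest-knot fallback
(logged); empty classes → skipped with warnings rather than NaNs.

## Known limitations

* The translation proxy is relative (px/s after derotation); forward
  translation along the optical axis produces radial parallax that the
  median partially discounts.
* Homography/essential model selection uses a fixed inlier-fraction
  threshold (0.6); heavily non-planar scenes with little texture may
  oscillate between paths.
* Pitch-only head rotation combined with lateral translation at a single
  depth is ambiguous in principle for any monocular method; the
  fronto-parallel prior resolves it in favor of the rotation the plane
  supports.
* Event-level (whole-segment) balancing is not implemented; balancing is
  sample-level within events.
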