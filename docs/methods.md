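# Methods

This note records the models behind `fishmot`, the parameter defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions that matter when reproducing results.

## Motion model and gating

Each track is a constant-velocity Kalman filter over
x = (cx, cy, a, h, vcx, vcy, va, vh), with a = width/height and the
measurement z = (cx, cy, a, h). The time step is one frame; frame-rate
effects belong to the data, not the filter.

Process noise follows the common tracking-by-detection convention of
scaling with box height: position/height standard deviations h/20 per
frame, velocity h/160, aspect 10⁻² (velocity 10⁻⁵). Track initialisation
uses zero velocity and a diagonal covariance at twice the position scale
and ten times the velocity scale.

Measurement noise is deliberately anisotropic: centroids h/20, but height
h/2 and aspect 1.0. Fish are non-rigid — a turning, tail-beating fish
changes its box height and aspect by tens of percent per frame while its
centroid moves smoothly — so shape innovations carry almost no association
information and must not dominate the Mahalanobis distance. With these
scales the Motion stage is effectively a position consistency test with a
weak shape prior. The gate is the chi-square 95th percentile at 4 degrees
of freedom, d² ≤ 9.4877.

The filter's innovation uses a Cholesky factorisation; a non-positive
definite innovation covariance (e.g. a collapsed state with h = 0) raises a
`NumericalError` rather than silently producing garbage. Covariances are
re-symmetrised after every step; a property test drives 1000 random
predict/update cycles and checks symmetry and positive semi-definiteness.

## Cascade association

Stages run in the fixed order Motion → IoU → Distance; each stage sees only
what earlier stages left unmatched, and each solves a min-cost Hungarian
assignment restricted to its gate (infeasible cells are masked with a large
finite constant before solving and any assignment landing on one is
discarded, so gated pairs are never returned). Ties are resolved
deterministically, so a given input always yields byte-identical output.

For the IoU and Distance stages the track's box is the **last observed
box re-centred at the Kalman-predicted position**, not the filter's
smoothed shape. The filter's shape state necessarily lags a deforming fish;
the one-frame-old observed shape is far more faithful, and using it removed
a class of association errors between closely swimming fish of different
sizes. The Distance gate is 1.0 × the mean of the two boxes' diagonals —
a scale-aware radius rather than a fixed pixel count.

Matched tracks emit the matched **detection's** box; the filter serves
association, while localisation in the output reflects the detector. Coasting
(unmatched) tracks emit the predicted box, flagged `coasted`; by default
coasted records are excluded from result files because standard evaluation
counts them as false positives, and `--keep-coasted` restores them.

## Lifecycle

- Birth: an unmatched detection with score > θ_new (default 0.4) founds a
  track; new tracks participate in matching from the next frame.
- Pre-filter: detections with score < pre_thresh (default 0.4) are dropped
  before any matching.
- Coasting: an unmatched track's score is multiplied by decay_factor
  (default 0.9) per missed frame. The decay form is a design choice; any
  monotone decay works, and the factor is config-exposed.
- Purge: a track is removed once it has missed **more than** max_age = 3
  consecutive frames — a track missing exactly 3 frames can still rematch
  on the 4th. The boundary is unit-tested from both sides. Identities are
  assigned once, strictly increasing, and never reused after a purge; there
  is no re-identification.

## Occlusion-head losses

`fishmot.losses` provides the occlusion-branch training losses as pure
array math (no autodiff, no network):

- Focal: mean of (1 − p)² · CE(p, y) with inputs clipped to
  [10⁻⁷, 1 − 10⁻⁷]. Note the modulation uses (1 − p)² regardless of the
  label, which down-weights *high-probability* predictions even when they
  are wrong negatives; the conventional label-aligned modulation
  ((1 − p_true)²) is available via `label_aligned=True`. Both reduce to
  cross-entropy when the modulation factor is 1.
- Dice: 1 − (2Σpy + ε)/(Σp + Σy + ε) with ε = 1 by default; the ε rescues
  the empty-mask case (loss 0 when both sides are empty).
- Adaptive weights: the printed sign rule, taken literally, collapses the
  weights to ±1 + 10⁻⁸ and can flip their sign; it is implemented as the
  only reading consistent with balanced contribution — a sign-driven
  multiplicative step w ← w·(1 − η·sign ∇), η = 0.05, floored at 10⁻⁸ and
  renormalised so α + β = 1.
- Total: w_base · (α·L_focal + β·L_dice); w_base multiplies the whole sum.

## Evaluation

- **CLEAR** matching persists previous-frame correspondences while their
  IoU stays ≥ the threshold (default 0.5), then optimally re-assigns the
  remainder maximising total IoU. An identity switch is counted when a
  ground-truth object's matched identity differs from its most recent
  previous match. This continuity rule controls IDSW semantics and matches
  the de-facto standard.
- **MOTP** is the mean (1 − IoU) over matched pairs — lower is better, 0 is
  perfect localisation.
- **Identity** metrics come from one global bipartite matching between
  ground-truth and predicted trajectories, dummy-augmented so any trajectory
  may remain unmatched; pair cost is the number of frames where the pair is
  not co-located at IoU ≥ threshold. On micro-scenes the counts are verified
  against exhaustive enumeration over all trajectory bijections.
- **HOTA** uses the standard two-pass matching: a first pass accumulates a
  global track-alignment score, a second per-frame Hungarian pass maximises
  alignment × IoU and keeps pairs with IoU ≥ α. A(c) = TPA/(TPA+FNA+FPA)
  with TPA the joint matches of c's identity pair across the sequence and
  FNA/FPA the remaining detections of either identity. The default is the
  single threshold α = 0.5; pass `alphas` (or `--hota-alphas`) for the
  multi-threshold average used by benchmark servers.
- Degenerate inputs (empty predictions, no matches) yield 0-valued metrics
  with explicit warnings in `evaluate`, so batch runs survive; the low-level
  operations (`mota`, `motp`, `mt_ml`) raise instead, since silent zeros
  there would mask bugs.

IoU itself is computed entirely from corner differences; mixing
width·height areas with corner arithmetic loses an ulp and makes identical
boxes compare at IoU < 1, which matters when asserting exact closure.

## Simulator

The generator emulates a dense-tank recording setup: a 1920 × 1080 px view
at 30 FPS, clips of 25 frames, 75 fish by default, body lengths mapped from
8–25 cm to 40–160 px box heights (a declared convenience — fish spanning a
modest fraction of a 1080 px frame), speeds 60–240 px/s.

Motion is a minimal zonal schooling model: repulsion (< 60 px), alignment
(< 180 px) and attraction (< 450 px) steer each fish's heading, scaled by a
schooling strength (default 0.5), with a per-frame turn-rate cap (0.3 rad)
and heading noise (0.05 rad). Fish near the boundary steer inward; a fish
whose centre still leaves the arena exits **for good** (absorbing exits —
consistent with short clips). A solid-body constraint keeps projected
centres at least 0.35 × mean body length apart: two fish cannot occupy the
same image location, though their elongated boxes still overlap heavily,
which is what drives occlusion events. Boxes are heading-dependent (wide
when swimming horizontally, tall when vertical) with a sinusoidal tail-beat
aspect modulation (±15%, 3 Hz) standing in for non-rigid deformation.

Corruption, applied per frame with dedicated RNG streams derived from the
scene seed: Gaussian corner jitter; independent dropout; occlusion dropout —
when two boxes overlap above a threshold the *smaller* box is dropped with
a given probability (a 2-D depth proxy: the rear fish is hidden); Poisson
clutter with low scores; and a score model starting at 1.0 minus penalties
for jitter and overlap. Presets (`normal`, `mf25-like`, `severe-occlusion`,
`severely-deformed`, `multi-density`) differ in corruption parameters —
plus a stronger tail beat for the deformation archetype, since deformation
is a ground-truth property, not a detector failure. The presets are
qualitative archetypes, not calibrated replicas of any real recording.

What passing tests on this simulator shows — and does not: the tracker and
metrics are exercised against geometric occlusion, dropout, jitter, clutter
and frame exits with exact, seeded ground truth; they are *not* exercised
against appearance ambiguity, illumination change, water turbidity, depth
crossings, or detector-specific error correlations, all of which real
footage adds.

## Problem sizes and determinism

Validation uses: exact closure (all metrics perfect) on uncorrupted 75-fish
× 25-frame scenes; oracle equality on random micro-scenes (≤ 4 objects,
≤ 5 frames) against exhaustive enumeration; 1000 random assignment matrices
up to 6 × 6 against permutation brute force; 200 seeded occlusion trials;
and dropout sweeps over 20 seeds at 20 fish. These sizes make every
brute-force oracle exact while keeping the full suite under a minute.
All randomness flows through `numpy.random.default_rng` seeded explicitly;
every entry point (simulator, pipeline, acceptance script) is deterministic
given its seed, and result files are byte-stable.

## Known limitations

- No appearance model: association is purely geometric, as in the cascade
  it implements; visually identical fish crossing while both undetected can
  swap without any signal to prevent it.
- No re-identification: a purged identity is gone; targets re-entering the
  frame get fresh identities.
- The Motion stage's shape components are nearly uninformative by design;
  a rigid-object deployment would want tighter shape noise.
- 2-D only: depth is handled solely by the smaller-box-hides heuristic in
  the simulator and not modelled in the tracker.
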