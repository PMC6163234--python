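# Methods

## Coordinate conventions

Skeleton joints live in a right-handed, y-up camera frame in meters
(`CameraConventions`, default vertical axis (0,1,0), horizontal axis
(1,0,0), 30 fps). A converter maps Kinect SDK camera space into this frame
by a half-turn about the vertical axis, preserving handedness. Bounding
boxes follow the convention of the extraction formulas — (x, y) is the
top-left corner in a *y-up* pixel frame, center (x + w/2, y − h/2) — with
`flip_box_y` for image-style y-down input.

## Geometric features

The lumbar angle α and cervical angle β are arccosines of the cosine
between a joint segment and the vertical axis, with the cosine clipped to
[−1, 1] to absorb floating-point drift. Degenerate (zero-length) segments
raise an error naming the joints rather than silently returning 0: a
coincident neck/spine-base pair indicates broken tracking, not an upright
spine.

The sight angle γ is *signed*: the rule literature places the healthy
gaze 15°–30° *below* horizontal, so a magnitude alone cannot express the
band. We define γ as the elevation of the gaze vector (head → screen) —
the angle between the gaze and the horizontal axis taken in the gaze's own
vertical plane, i.e. arcsin of its normalized vertical component — which
is negative when the screen lies below eye level. The head joint proxies
the eye; no eye joint is tracked. The sight distance δ is the Euclidean
head–screen distance.

Box overlap uses signed extents clamped at zero. An unclamped
absolute-value product would report a positive "overlap" for disjoint
rectangles, which would defeat its role as a co-location test; clamping
makes overlap(b, b) = area(b) and overlap = 0 exactly for disjoint boxes,
verified against a pixel-grid counting oracle.

A lateral (out-of-sagittal-plane) spine angle supplements the eight
features for the body-sideways subtype only: a sideways lean of the same
magnitude produces the same α as a forward lean, so the in-plane angle
alone cannot distinguish them.

## Scene association and the seated gate

The person–chair–screen triple is resolved per frame: persons (in
instance-id order) claim the chair with the greatest box overlap among
chairs whose overlap is at least 0.2 of the person-box area (ties: smaller
center distance, then smaller id; chairs are exclusive), and the claimed
chair takes the nearest screen within 4 chair diagonals. A pairing is
sticky: it survives up to 5 consecutive frames of gate failure before
re-association, so brief detector dropouts do not churn the assignment.
The association is deterministic and invariant to detection order.

A person counts as *seated* when the person–chair overlap is ≥ 0.2 of the
person-box area and the center distance is ≤ 1 chair diagonal. These
gates are configuration values, not literature constants: the underlying
observation is only that the spatial-relation features are stable while
seated and change when the person stands or walks away, so the defaults
were chosen once to make the seated/standing transition unambiguous on the
synthetic layouts and are exposed in `AssociationConfig`.

## Feature matrix and scaling

Clustering operates on seated frames with all eight features valid.
Features with missing inputs (no screen point, unassigned chair) are
flagged invalid as NaN — never zero-filled, since a zero pixel distance or
a zero sight distance is a strong (and wrong) statement. Because the
features mix radians, meters, pixels and pixels², columns are z-scored
before clustering (constant columns get scale 1); min-max and no scaling
are available by configuration, and the fitted parameters support an exact
inverse transform, which cluster labeling relies on.

## Gaussian-mixture clustering

The mixture is fitted by EM with the standard updates: E-step posteriors
(responsibilities) in log-space with log-sum-exp, M-step
responsibility-weighted means, covariances and weights. Numerical
choices:

* densities are evaluated through a Cholesky factorization, never an
  explicit covariance inverse;
* every covariance receives a ridge εI (default ε = 1e−6) — with
  near-constant feature columns (e.g. a screen that never moves) the
  sample covariance is singular without it;
* convergence is declared when the total log-likelihood changes by less
  than `tol` (default 1e−7) or after `max_iter` = 500 iterations; the
  trace records the per-iteration log-likelihood, which is non-decreasing;
* initialization (not specified by the clustering formulation itself)
  defaults to k-means++-style D²-weighted seeding of the means from the
  data, the global covariance for every component, and uniform weights;
  `random_state` makes fits fully deterministic;
* a component whose responsibility mass vanishes is re-seeded from the
  point farthest from the surviving means (or raises, by configuration);
* hard assignment is the row-wise argmax with ties to the lowest index.

Default k = 2, matching the two behavioral regions the discrimination
stage distinguishes (healthy vs unhealthy); k is configurable. Model
selection over k (BIC/AIC) is out of scope. The covariance update is the
standard responsibility-weighted outer-product estimator — the unique
stationary point of the log-likelihood in Σᵢ.

Cluster semantics come from the rules, not from labels: each component
mean is inverse-transformed to original units, interpreted as a seated
frame, and classified; the component inherits that verdict. On separable
synthetic data this agrees with the majority ground truth of each
cluster's members (tested).

## Rule discrimination and subtypes

A seated frame is unhealthy iff any rule fires: α > 20° (strict — 20°
exactly is healthy), β > 20°, δ outside the closed band [0.40 m, 0.70 m],
or γ outside [−30°, −15°]. All firing rules are reported. A frame whose
gaze features are invalid (no screen) is `unknown`, never unhealthy:
missing detections must not create false alarms. Worked magnitudes for
context: a healthy reading pose sits near α ≈ 0.15 rad (8.59°) and an
unhealthy forward lean near α ≈ 0.58 rad (33.23°), β ≈ 0.36 rad (20.63°),
δ ≈ 0.37 m.

Subtypes are a fixed-order decision list (first match wins): bend over
(α > 50°) → looking up (γ > 0) → lean forward (α, β over threshold and δ
below band) → lean backward (α, β over and δ above) → small sight distance
(only δ below) → body sideways (lateral lean > 15°) → hold head (β over
with α within) → none. The ordering puts the most specific/extreme
patterns first; the secondary bounds (50°, 15°) are package defaults, not
literature constants, and are configurable. The hold-head rule is a
stand-in — truly detecting a propped head would need hand joints the
method does not track.

Reported healthy sight distances in the source material vary (a healthy
example at ≈0.86 m, a narrative "about 80 cm") and are not all inside the
cited 40–70 cm ergonomic band; the defaults follow the cited band and the
band is configurable.

## Temporal smoothing

Per-frame labels are grouped into maximal runs. An unhealthy run shorter
than `min_event_frames` (default 150 frames = 5 s at 30 fps) is a
transient: it is relabelled to the preceding run's state (the following
run's at the start of a sequence; `unknown` when the sequence holds
nothing else) and never emitted as an unhealthy event. Events partition
the frame range; each unhealthy event carries the modal subtype of its
frames (alphabetical tie-break) and the mean feature vector over its span.
Healthy/not-sitting/unknown runs have no minimum duration.

## Synthetic generator

The generator emulates the assumed capture setup — a side-mounted depth
camera about 1.4 m high viewing a seated person 2–3 m away at 30 fps,
videos of hundreds of frames — and constructs streams by *inverse
geometry*: per-frame α/β are drawn from a class's truncated normal and the
joints are placed so the realized angles equal the draws exactly (torso
0.45 m, neck segment 0.25 m, spine base at (0, 0.6 m, 2.5 m)). The screen
point is fixed per video, placed from the noise-free head pose at the
class-mean γ/δ, so gaze features are exact at zero noise and deviate by
the order of the joint noise otherwise. Box layouts follow a seated
template (person overlapping the chair, screen a desk-width away) with
small uniform pixel jitter.

Class ranges straddle the rule thresholds with a margin — healthy
α ~ N(8°, 3°) truncated at 18°, lean-forward α ~ N(33°, 4°) truncated
above 22°, and so on, matching the magnitudes of the worked examples — so
with the default noise every frame of an unhealthy class violates its
defining rule and every healthy frame violates none. That is by design:
the generator provides ground truth the pipeline must *recover*, not a
hard corner case. Consequences for interpretation: passing the synthetic
benchmark demonstrates correct plumbing, association, rule geometry and
event logic, **not** performance on real tracked skeletons, which carry
correlated tracking error, occlusion dropouts, borderline postures and
detector noise none of which are modelled. Cluttered scenes add
distractor screens/chairs/persons placed so the association gates must
exclude them; distractors never overlap a chair, so their exclusion tests
the rule, not chance geometry.

Everything is seeded (`numpy.random.default_rng`), with per-video seeds
drawn from a master seed; no global random state is used or mutated.

## Problem sizes in the default test run

The acceptance-style checks use desk-scale inputs chosen as comfortable
defaults: boundary sweeps at 0.01° / 0.1 cm resolution, EM parameter
recovery on n = 200 two-blob data, and an end-to-end benchmark of 10
videos per class × 8 classes × 600 frames. These sizes are the package's
own defaults for a quick, deterministic health check; larger runs only
tighten the same statistics.

## Known limitations

* Single tracked subject per analysis pass (the association handles
  multiple persons; the pipeline analyzes one `person_id` at a time).
* The screen reference point is a single static 3-D point per scene;
  moving or multiple screens in 3-D are not modelled (multiple screen
  *detections* are handled in pixel space).
* The eye is proxied by the head joint; γ/δ inherit that offset.
* Subtype rules are deterministic surrogates for qualitative class
  descriptions; borderline multi-violation frames resolve by list order.
* The GMM assumes elliptical clusters in standardized feature space;
  strongly multimodal behavior within one health state argues for larger k.
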