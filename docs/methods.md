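# Methods

## Coordinate and angle conventions

All geometry lives in image coordinates: origin top-left, x right, y *down*.
The anti-gravity ("up") reference is the fixed vector (0, −1); the camera is
assumed level on a tripod, and the gravity reference is a parameter of the
angle functions for setups where it is not.  Angles are degrees everywhere;
radians never cross a module boundary, because every scoring threshold in
the field is stated in degrees.

Every angle is the arccosine of the normalised dot product of its two
defining vectors, evaluated in the atan2(|cross|, dot) form, which is the
same value at full floating-point precision near 0° and 180°.  Deviation
angles (neck θ₁, trunk θ₄, shank-ground θ₇) reference the fixed up/horizontal
axes and are therefore deliberately *not* invariant under image rotation;
included angles (θ₂, θ₃, θ₅, θ₆, wrist) are.  Both behaviours are asserted by
tests.  All angles are invariant under translation and uniform scaling, so no
pixel calibration is required.

Specific choices:

- **Head point for θ₁** — midpoint of the two ears when both are detected,
  else the nose.  BODY_25 has no "top of head" landmark; the ears are the
  most rigid available proxy and the nose is an acceptable fallback with a
  small forward bias.
- **θ₇ folding** — the shank-ground inclination is folded into [0, 90] by
  default (the REBA-relevant quantity); an unfolded [0, 180] convention is
  available via a flag.
- **Wrist angle** — BODY_25 carries no hand point, so the wrist deviation is
  optional: the accepted label set is extended with `RHand`/`LHand`, and when
  no hand point exists the wrist sub-score falls back to a configured default
  of 1 (wrists are near-static in lifting tasks).
- **Undefined values** — any angle whose keypoints are missing is NaN, and
  NaN propagates to an explicit "unscorable frame" flag rather than a guess.

## Cleaning defaults

Keypoints below a confidence threshold (default 0.1 in the CLI) are marked
missing.  Runs of ≤ 5 consecutive missing frames (≈ 0.17 s at 30 fps) flanked
by detections are filled by linear interpolation, with the filled confidence
set to the minimum of the flanks; longer and boundary runs stay missing.
Angle series are smoothed with a centered moving median, window 5 frames,
which removes single-frame detector spikes without rounding sustained peaks;
window 1 disables smoothing.  Source data for these choices does not exist in
the protocol this mirrors; they are the package's own defaults and are all
configurable.

## REBA engine

Sub-score rules follow the standard worksheet, with two deliberate choices:

- **Upright tolerance** — the trunk scores 1 within ±5° of vertical (then 2
  to 20°, 3 to 60°, 4 beyond).  Without a tolerance, keypoint jitter would
  make a perfectly upright trunk unreachable; the threshold is configurable.
- **Additive load and muscle-use per group** — Score A = Table A + load +
  muscle-use(A) and Score B = Table B + coupling + muscle-use(B).  Some
  worksheet variants fold muscle use into the activity score instead; the
  additive-per-group layout is the one that reproduces this workflow's
  published score sheets, and those sheets are regression tests.

The Table A (5×3×4), Table B (6×2×3) and Table C (12×12) matrices are the
standard published REBA matrices; exhaustive monotonicity and bound checks
run over every cell.  Score A/B are clamped to 12 before the Table C lookup
(defensive; unreachable with valid inputs).  The total is capped at 15 and
maps to action levels 0–4 (negligible / low / medium / high / very high)
partitioning [1, 15].

Twist, side-bend, abduction, shoulder-raise and support flags cannot be
derived from a sagittal 2D projection, so they are configuration inputs
defaulting to false.  Load in kg maps to the force score as < 5 kg → 0,
5–10 → 1, > 10 → 2, +1 for shock.  When scoring from angles, the default
side policy is `max`: both sides are scored and the worse total kept (ties
keep the left side) — the conservative choice for risk screening.

## Comfort gradient

Boundaries are stored per part as four ordered angles (normal,
easy-to-moderate, moderate-to-laborious, most-laborious) with a direction:
discomfort grows with the deviation angle for neck and trunk (increasing)
and as the included angle closes for the knee (decreasing).  Intervals are
lower-closed on the easy side — e.g. neck easy = [17, 49), moderate =
[49, 57), strenuous = [57, 60] — and the knee mirrors them upper-closed.
Angles outside [normal, most-laborious] grade as `normal` or
`beyond_strenuous`; classification never clamps.

`fit_thresholds` estimates each boundary as the labelled cell mean (≥ 2
samples per cell), reports the cell SD, and infers the direction from the
ordering of the means, erroring on non-monotone input.  The ANOVA is the
textbook one-way sum-of-squares decomposition computed from its definition
(SS_between + SS_within = SS_total to 1e-9 is a test invariant), with the
p-value from the F distribution; it is cross-checked against an independent
implementation in the test suite.  Tukey-HSD delegates to a
studentized-range implementation that uses the Tukey-Kramer form for unequal
group sizes.  Note that with the shipped between-subject SDs (≈ 3–5°) and 42
samples per level, the closest neck boundary pair (57° vs 60°) is *not*
separable at p < 0.001; separability at that level requires within-level
spread well below the 3° gap, which is how the separability tests are
constructed.

## Synthetic motion generator

The simulator emulates the study conditions the package targets: sagittal
bend-and-reach motion of a single adult figure filmed at 30 fps in full-HD
image coordinates.  Segment lengths default to standard anthropometric
fractions of stature (trunk 0.288 H, upper arm 0.186 H, forearm 0.146 H,
thigh 0.245 H, shank 0.246 H, …), with the default stature 1.64 m (the
cohort mean) and a default scale of 500 px/m.

A pose is commanded by exactly the angles the kinematics module measures;
the chain is rooted at the mid-hip, so the shank-ground inclination θ₇ is a
*derived* quantity (commanding it independently would over-determine the
chain and make exact round-trip recovery impossible).  Round-trip identity —
forward kinematics then measurement recovers every commanded angle to
≤ 1e-6° at zero noise — is tested over 1000 random poses, along with
rigid-segment preservation.

Noise is isotropic Gaussian pixel jitter, i.i.d. per keypoint and frame,
with confidences drawn Normal(0.9, 0.05) clipped to [0.05, 1] and Bernoulli
dropout (dropped keypoints get confidence 0).  This is the simplest
defensible stand-in for detector jitter; it does **not** reproduce real
estimator failure modes (correlated drift, left/right swaps, occlusion-long
dropouts, depth-dependent scale error), so passing tests bound geometric
correctness and noise robustness of the *pipeline*, not accuracy of any
particular pose estimator on real video.

Presets are smoothstep-interpolated keyframe trajectories over the phase
structure approach → reach/bend → grasp → return, with nominal durations
(no timing claims):

- `preset_take_high(shelf_cm ∈ {120,130,140,150}, stature)` — the peak
  shoulder elevation is 90° plus the arcsine of the shelf's height above
  shoulder level across the arm's reach, making the peak strictly increasing
  in shelf height and strictly decreasing in stature, the qualitative
  pattern reported for real subjects.
- `preset_bend_low(stature, deep_squat=False)` — the default depth places
  the peak trunk deviation (36°) and knee included angle (132°) inside the
  strenuous comfort bands; `deep_squat=True` uses the full floor-pickup
  depth (trunk 70°, knee 110°) that drives the high-risk REBA band, matching
  the deep-bend worksheet rows (trunk sub-score 4 requires > 60°).  The two
  depths exist because the comfort-band limits and the deep-bend worksheet
  scores describe different trunk depths; both are single keyword arguments
  away.

## Reporting

Phase segmentation is annotation-driven (the behaviour phases are defined
observationally, not algorithmically); absent annotations, the whole
sequence is one phase.  The representative posture per phase is the frame
with the maximum REBA total (conservative; a mean-posture alternative can be
derived from the risk-curve CSV).  A phase is flagged high-risk when its
representative action level is ≥ 3, i.e. total ≥ 8.  Every number in the
report is produced by a library operation; the report layer only formats.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic sequences of
~100–300 frames and cohorts of 42 samples per cell — comfortably
representative for a 1–15 integer scoring system whose matrices are checked
exhaustively.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give byte-identical CSV
outputs end to end.

## Known limitations

- Strictly sagittal 2D: no abduction/adduction or axial rotation; the flags
  REBA needs for those are user inputs.
- The comfort gradient ships with cohort-level boundaries for one elderly
  population and one task family; refit before applying it elsewhere.
- The upright-tolerance and cleaning defaults are heuristics for detector
  jitter, not estimates from data.
- Multi-person scenes keep only the highest-confidence person; there is no
  tracking across frames.
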