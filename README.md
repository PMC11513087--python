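# rebakit

Ergonomic posture-risk assessment from 2D pose keypoints.

`rebakit` implements a video-based workflow for grading the risk of
work-related musculoskeletal disorders (WMSDs) during bend-and-reach tasks —
the kind of repeated cabinet-reaching and floor-pickup motions that load the
trunk, knees and shoulders of elderly users in a kitchen.  It is aimed at
ergonomics and human-factors researchers who already have 2D skeletal
keypoints (e.g. from a BODY_25-style pose estimator) and want reproducible
joint angles, REBA scores and comfort grades, without spreadsheets or manual
worksheet lookups.

The pipeline has four stages, each usable on its own:

1. **pose I/O** — read per-frame pose-estimator JSON (BODY_25 dialect) or a
   plain keypoint CSV; filter by confidence; interpolate short occlusion gaps.
2. **kinematics** — sagittal joint angles per frame: neck deviation θ₁,
   upper-arm angle θ₂, elbow included angle θ₃, trunk deviation θ₄, hip
   included angle θ₅, knee included angle θ₆ and shank-ground inclination θ₇
   (plus optional wrist deviation), with moving-median smoothing and
   range/peak summaries.
3. **REBA engine** — the full Rapid Entire Body Assessment: angle → sub-score
   rules for trunk/neck/legs (Group A) and upper arm/forearm/wrist (Group B),
   the published Table A/B/C matrices, load, coupling, muscle-use and
   activity adjustments, and the 1–15 total with its action level
   (0 negligible … 4 very high).
4. **comfort gradient** — classify neck, trunk and knee angles into
   easy / moderate / strenuous bands (shipped boundaries: neck 17/49/57/60°,
   trunk 1/12/28/40°, knee 179/151/139/126° included), refit the boundaries
   from labelled samples, and check level separability with one-way ANOVA
   and Tukey-HSD.

A forward-kinematic stick-figure simulator (`rebakit.synthetic`) generates
bend-and-reach keypoint sequences with known ground-truth angles, detector
noise and dropout, so the whole pipeline is testable without video data.

## The scoring model

For each posture, sub-scores are read off the joint angles, e.g. trunk
deviation ≤5° → 1, ≤20° → 2, ≤60° → 3, else 4 (+1 for twist/side-bend); neck
1 for flexion ≤20° else 2; legs get +1 for knee included angle 120–150° and
+2 below 120°.  Then

    Score A = TableA(trunk, neck, legs) + load + muscle_use_A
    Score B = TableB(upper_arm, forearm, wrist) + coupling + muscle_use_B
    Score C = TableC(Score A, Score B)
    total   = Score C + activity          (capped at 15)

and the total maps to an action level: 1 → negligible, 2–3 → low,
4–7 → medium, 8–10 → high (act now), 11–15 → very high.

## Worked example

`examples/01_score_a_posture.py` builds a deep floor-pickup posture (trunk
bent 70°, knees at 110° included), measures the angles back from the
generated skeleton and scores it:

```
trunk deviation 70.0 deg, neck 25.0 deg, knee included 110.0 deg
  ...
  score_a: 8
  score_b: 4
  score_c: 9
  total: 9
  action_level: 3
  risk: high
REBA total 9 -> action level 3 (high): immediate improvement needed
```

Reading the numbers: trunk 70° scores 4, neck 25° scores 2, knees at 110°
add two leg points (score 3); with one muscle-use point Group A totals 8.
The reaching arm (45° shoulder, elbow nearly straight) gives Group B 4.
Table C combines them to 9 — a *high-risk* posture: if this bend is repeated
often, the load on trunk and knees warrants redesign or external support.

`examples/02_simulate_and_assess.py` runs the same assessment end to end on
a simulated noisy sequence and prints a per-phase report (the bend peak is
flagged high-risk, the approach and return phases are not), and
`examples/03_comfort_gradient.py` grades angles on the comfort gradient and
refits its boundaries from a simulated labelled cohort.

There is also a thin CLI over the same functions:

```bash
rebakit simulate --preset bend_low --deep-squat --seed 7 --out sim/
rebakit analyze sim/keypoints.csv --out assessment/
rebakit gradient samples.csv --out gradient/
```

## Layout

```
src/rebakit/      skeleton, pose_io, kinematics, reba, comfort, synthetic,
                  report, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   model assumptions, defaults and limitations
```
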