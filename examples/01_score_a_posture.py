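"""Score a single posture with REBA, from commanded joint angles.

Builds a deep floor-pickup posture with the stick-figure model, measures its
sagittal joint angles from the generated keypoints, and runs the full REBA
worksheet on them.  The printed sheet shows each body-part sub-score, the
group scores A/B, the combined score C, and the 1-15 total with its action
level: 8 or more means "high risk, act now".
"""

from rebakit import (
    BodyModel, PosturePose, RebaConfig, compute_angles, forward_kinematics,
    score_frame,
)

body = BodyModel.from_stature(1.64)  # average stature of the study cohort, m
pose = PosturePose(trunk=70, neck=25, shoulder_r=45, shoulder_l=20,
                   elbow_r=150, elbow_l=160, hip_r=60, hip_l=60,
                   knee_r=110, knee_l=110)

angles = compute_angles(forward_kinematics(body, pose))
print(f"trunk deviation {angles.theta4_trunk:.1f} deg, "
      f"neck {angles.theta1_neck:.1f} deg, "
      f"knee included {angles.theta6_thigh_calf_R:.1f} deg")

# whole-body muscles engaged during the bend -> muscle-use point for group A
sheet = score_frame(angles, RebaConfig(muscle_use_a=1))
for key, value in sheet.as_dict().items():
    print(f"  {key}: {value}")
print(f"REBA total {sheet.total} -> action level {sheet.action_level} "
      f"({sheet.risk.value}): immediate improvement needed"
      if sheet.action_level >= 3 else f"REBA total {sheet.total}")
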