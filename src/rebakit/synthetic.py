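"""Forward-kinematic stick-figure simulator for sagittal bend-and-reach motion.

The generator is the package's stand-in for filmed keypoint data: it places a
2D articulated figure (segment lengths as standard anthropometric fractions
of stature) in image coordinates, drives it through phase-structured
bend-and-reach trajectories, and emits the same keypoint sequences the
readers consume — optionally with Gaussian pixel noise, detector-style
confidence values and keypoint dropout — together with the noiseless
ground-truth joint angles.

A pose is commanded by the angles the kinematics module measures: trunk and
neck deviation from vertical, and included angles at shoulder, elbow, hip and
knee per side.  The shank-ground inclination is *not* a free command — in a
chain rooted at the hip it is fully determined by the trunk, hip and knee
angles — and is reported as a derived quantity instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .kinematics import JointAngleSeries, compute_angles
from .skeleton import Keypoint2D, MotionSequence, SkeletonFrame, SubjectInfo

__all__ = [
    "BodyModel",
    "PosturePose",
    "TrajectorySpec",
    "NoiseModel",
    "forward_kinematics",
    "generate_sequence",
    "preset_take_high",
    "preset_bend_low",
    "SHELF_HEIGHTS_CM",
]

#: Upper-cabinet shelf heights exercised by the reach preset, in cm.
SHELF_HEIGHTS_CM = (120, 130, 140, 150)

# Anthropometric segment lengths as fractions of stature.
_FRACTIONS = {
    "neck_to_head": 0.093,   # neck (mid-shoulder) to ear level
    "trunk": 0.288,          # mid-hip to neck
    "upper_arm": 0.186,
    "forearm": 0.146,
    "hand": 0.108,
    "thigh": 0.245,
    "shank": 0.246,
}


@dataclass(frozen=True)
class BodyModel:
    """Segment lengths (m) plus the image-space scale and root position."""

    neck_to_head: float
    trunk: float
    upper_arm: float
    forearm: float
    hand: float
    thigh: float
    shank: float
    px_per_m: float = 500.0
    root_px: tuple[float, float] = (960.0, 540.0)  # mid-hip, image coordinates

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in _FRACTIONS and getattr(self, f.name) <= 0:
                raise ValueError(f"segment length {f.name} must be > 0")
        if self.px_per_m <= 0:
            raise ValueError("px_per_m must be > 0")

    @classmethod
    def from_stature(cls, stature_m: float = 1.64, **overrides) -> "BodyModel":
        """Proportional body from a stature (default: study cohort mean)."""
        if stature_m <= 0:
            raise ValueError("stature must be > 0")
        kw = {name: frac * stature_m for name, frac in _FRACTIONS.items()}
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class PosturePose:
    """Commanded joint angles for one posture, degrees.

    ``trunk`` and ``neck`` are deviations from the anti-gravity axis
    (0 = upright); the remaining angles are included angles at the joint
    (shoulder: arm vs trunk line, 0 = hanging; elbow/hip/knee: 180 =
    straight).  ``wrist_*`` is the hand's deviation from the straight
    forearm line.
    """

    trunk: float = 0.0
    neck: float = 0.0
    shoulder_l: float = 0.0
    shoulder_r: float = 0.0
    elbow_l: float = 180.0
    elbow_r: float = 180.0
    hip_l: float = 180.0
    hip_r: float = 180.0
    knee_l: float = 180.0
    knee_r: float = 180.0
    wrist_l: float = 0.0
    wrist_r: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 180.0):
                raise ValueError(f"{f.name} must be in [0, 180] degrees, got {v!r}")

    @staticmethod
    def lerp(a: "PosturePose", b: "PosturePose", t: float) -> "PosturePose":
        return PosturePose(**{
            f.name: getattr(a, f.name) + t * (getattr(b, f.name) - getattr(a, f.name))
            for f in fields(PosturePose)
        })


def _rot_fwd(v: tuple[float, float], deg: float) -> tuple[float, float]:
    """Rotate a vector by ``deg`` toward +x (forward) in image coordinates."""
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return (v[0] * c + v[1] * s, -v[0] * s + v[1] * c)


def forward_kinematics(body: BodyModel, pose: PosturePose,
                       frame_index: int = 0, fps: float = 30.0) -> SkeletonFrame:
    """Place every keypoint of the figure for one commanded pose.

    The chain is rooted at the mid-hip; forward lean is toward +x.  All
    confidences are 1.  The resulting frame measures back exactly to the
    commanded angles through the kinematics module.
    """
    s = body.px_per_m
    hip = body.root_px
    up = (math.sin(math.radians(pose.trunk)), -math.cos(math.radians(pose.trunk)))
    neck = (hip[0] + body.trunk * s * up[0], hip[1] + body.trunk * s * up[1])
    head_dir = (math.sin(math.radians(pose.neck)), -math.cos(math.radians(pose.neck)))
    ear = (neck[0] + body.neck_to_head * s * head_dir[0],
           neck[1] + body.neck_to_head * s * head_dir[1])
    nose = (neck[0] + 1.1 * body.neck_to_head * s * head_dir[0],
            neck[1] + 1.1 * body.neck_to_head * s * head_dir[1])

    pts: dict[str, tuple[float, float]] = {
        "MidHip": hip, "Neck": neck, "REar": ear, "LEar": ear,
        "Nose": nose, "REye": nose, "LEye": nose,
        "RHip": hip, "LHip": hip, "RShoulder": neck, "LShoulder": neck,
    }

    down = (-up[0], -up[1])  # neck -> mid-hip direction (the trunk line)
    for side, sh_a, el_a, wr_a in (("R", pose.shoulder_r, pose.elbow_r, pose.wrist_r),
                                   ("L", pose.shoulder_l, pose.elbow_l, pose.wrist_l)):
        arm_dir = _rot_fwd(down, sh_a)
        elbow = (neck[0] + body.upper_arm * s * arm_dir[0],
                 neck[1] + body.upper_arm * s * arm_dir[1])
        fore_dir = _rot_fwd((-arm_dir[0], -arm_dir[1]), el_a)
        wrist = (elbow[0] + body.forearm * s * fore_dir[0],
                 elbow[1] + body.forearm * s * fore_dir[1])
        hand_dir = _rot_fwd(fore_dir, wr_a)
        hand = (wrist[0] + body.hand * s * hand_dir[0],
                wrist[1] + body.hand * s * hand_dir[1])
        pts[f"{side}Elbow"] = elbow
        pts[f"{side}Wrist"] = wrist
        pts[f"{side}Hand"] = hand

    for side, hip_a, knee_a in (("R", pose.hip_r, pose.knee_r),
                                ("L", pose.hip_l, pose.knee_l)):
        thigh_dir = _rot_fwd(up, hip_a)
        knee = (hip[0] + body.thigh * s * thigh_dir[0],
                hip[1] + body.thigh * s * thigh_dir[1])
        shank_dir = _rot_fwd((-thigh_dir[0], -thigh_dir[1]), knee_a)
        ankle = (knee[0] + body.shank * s * shank_dir[0],
                 knee[1] + body.shank * s * shank_dir[1])
        toe = (ankle[0] + 0.05 * s, ankle[1])
        pts[f"{side}Knee"] = knee
        pts[f"{side}Ankle"] = ankle
        pts[f"{side}Heel"] = ankle
        pts[f"{side}BigToe"] = toe
        pts[f"{side}SmallToe"] = toe

    kps = {name: Keypoint2D(name, x, y, 1.0) for name, (x, y) in pts.items()}
    return SkeletonFrame(frame_index, frame_index / fps, kps)


@dataclass(frozen=True)
class TrajectorySpec:
    """Keyframed motion: ordered (time s, pose) pairs, held at the ends."""

    keyframes: tuple[tuple[float, PosturePose], ...]
    fps: float = 30.0
    duration_s: float | None = None
    interpolation: str = "smoothstep"  # or "linear"
    task: str = ""

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ValueError("need at least one keyframe")
        times = [t for t, _ in self.keyframes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("keyframe times must be strictly increasing")
        if self.interpolation not in ("linear", "smoothstep"):
            raise ValueError("interpolation must be 'linear' or 'smoothstep'")
        dur = self.duration_s if self.duration_s is not None else times[-1]
        if dur < times[-1]:
            raise ValueError("duration shorter than the last keyframe time")
        object.__setattr__(self, "duration_s", dur)

    def pose_at(self, t: float) -> PosturePose:
        kf = self.keyframes
        if t <= kf[0][0]:
            return kf[0][1]
        if t >= kf[-1][0]:
            return kf[-1][1]
        for (t0, p0), (t1, p1) in zip(kf, kf[1:]):
            if t0 <= t <= t1:
                u = (t - t0) / (t1 - t0)
                if self.interpolation == "smoothstep":
                    u = u * u * (3.0 - 2.0 * u)
                return PosturePose.lerp(p0, p1, u)
        raise AssertionError("unreachable")

    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps)) + 1


@dataclass(frozen=True)
class NoiseModel:
    """Detector-style corruption: pixel jitter, confidence draw, dropout."""

    gaussian_sd_px: float = 0.0
    confidence_mean: float = 0.9
    confidence_sd: float = 0.05
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd_px < 0:
            raise ValueError("gaussian_sd_px must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be in [0, 1]")


def _corrupt(frame: SkeletonFrame, noise: NoiseModel, rng: np.random.Generator) -> SkeletonFrame:
    kps = {}
    for label in sorted(frame.keypoints):  # fixed order for determinism
        kp = frame.keypoints[label]
        if rng.random() < noise.dropout_prob:
            kps[label] = kp.as_missing()
            continue
        dx, dy = rng.normal(0.0, noise.gaussian_sd_px, size=2) if noise.gaussian_sd_px > 0 else (0.0, 0.0)
        conf = float(np.clip(rng.normal(noise.confidence_mean, noise.confidence_sd), 0.05, 1.0))
        kps[label] = Keypoint2D(label, kp.x + dx, kp.y + dy, conf)
    return SkeletonFrame(frame.frame_index, frame.timestamp, kps)


def generate_sequence(
    body: BodyModel,
    traj: TrajectorySpec,
    noise: NoiseModel | None = None,
    subject: SubjectInfo | None = None,
) -> tuple[MotionSequence, JointAngleSeries]:
    """Simulate a keypoint sequence plus its noiseless ground-truth angles.

    Deterministic for a given ``noise.seed``.  Ground truth is measured from
    the clean forward-kinematic frames (identical to the commanded angles);
    the returned sequence carries the corrupted keypoints.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    clean_frames, noisy_frames = [], []
    for i in range(traj.n_frames()):
        t = i / traj.fps
        frame = forward_kinematics(body, traj.pose_at(t), frame_index=i, fps=traj.fps)
        clean_frames.append(frame)
        noisy_frames.append(_corrupt(frame, noise, rng))
    truth = JointAngleSeries([compute_angles(f) for f in clean_frames],
                             fps=traj.fps, smoothing="none")
    seq = MotionSequence(noisy_frames, fps=traj.fps,
                         subject=subject or SubjectInfo(), task=traj.task)
    return seq, truth


# ---------------------------------------------------------------------------
# presets


_STAND = PosturePose(trunk=2.0, neck=5.0, shoulder_l=5.0, shoulder_r=5.0,
                     elbow_l=175.0, elbow_r=175.0, hip_l=178.0, hip_r=178.0,
                     knee_l=178.0, knee_r=178.0)


def _reach_peak_shoulder(shelf_height_cm: float, stature_m: float) -> float:
    """Shoulder elevation needed to reach a shelf: 90° (horizontal arm) plus
    the elevation of the shelf above shoulder height across the arm's reach."""
    shoulder_h = 0.818 * stature_m
    reach = (_FRACTIONS["upper_arm"] + _FRACTIONS["forearm"]
             + 0.5 * _FRACTIONS["hand"]) * stature_m
    ratio = (shelf_height_cm / 100.0 - shoulder_h) / reach
    return 90.0 + math.degrees(math.asin(max(-1.0, min(1.0, ratio))))


def preset_take_high(shelf_height_cm: int, stature_m: float = 1.64,
                     fps: float = 30.0) -> TrajectorySpec:
    """Reach to an upper-cabinet shelf and place the object on the counter.

    Supported shelf heights: 120, 130, 140, 150 cm.  The peak shoulder angle
    grows with shelf height and shrinks with stature (a taller subject needs
    less elevation for the same shelf), mirroring the reported cohort trend.
    Phases: stand → reach up → grasp → lower to counter → stand.
    """
    if shelf_height_cm not in SHELF_HEIGHTS_CM:
        raise ValueError(
            f"unsupported shelf height {shelf_height_cm}; presets: {SHELF_HEIGHTS_CM}"
        )
    peak_sh = _reach_peak_shoulder(shelf_height_cm, stature_m)
    counter_sh = max(20.0, _reach_peak_shoulder(85, stature_m) + 25.0)
    reach = replace(_STAND, neck=10.0, shoulder_r=peak_sh, elbow_r=170.0, trunk=4.0)
    grasp = replace(reach, elbow_r=160.0)
    lower = replace(_STAND, neck=8.0, shoulder_r=counter_sh, elbow_r=130.0)
    return TrajectorySpec(
        keyframes=((0.0, _STAND), (1.0, reach), (1.6, grasp),
                   (3.0, lower), (4.0, _STAND)),
        fps=fps, duration_s=4.5, interpolation="smoothstep",
        task=f"take_high_{shelf_height_cm}cm",
    )


def preset_bend_low(stature_m: float = 1.64, fps: float = 30.0,
                    deep_squat: bool = False) -> TrajectorySpec:
    """Bend down to pick an object off the floor and rise again.

    The default depth places the peak trunk deviation and knee flexion inside
    the strenuous comfort-gradient bands (trunk 28–40°, knee included
    126–139°).  ``deep_squat=True`` produces the full floor-pickup depth
    (trunk ≈ 70°, knee ≈ 110°) that drives the high-risk REBA band.
    Phases: stand → bend → grasp → rise → stand.
    """
    if deep_squat:
        bend = PosturePose(trunk=70.0, neck=25.0, shoulder_l=20.0, shoulder_r=45.0,
                           elbow_l=160.0, elbow_r=150.0, hip_l=60.0, hip_r=60.0,
                           knee_l=110.0, knee_r=110.0)
    else:
        bend = PosturePose(trunk=36.0, neck=30.0, shoulder_l=15.0, shoulder_r=40.0,
                           elbow_l=165.0, elbow_r=150.0, hip_l=100.0, hip_r=100.0,
                           knee_l=132.0, knee_r=132.0)
    grasp = replace(bend, elbow_r=max(0.0, bend.elbow_r - 15.0))
    return TrajectorySpec(
        keyframes=((0.0, _STAND), (1.2, bend), (1.8, grasp),
                   (3.2, _STAND)),
        fps=fps, duration_s=3.5, interpolation="smoothstep",
        task="bend_low_deep" if deep_squat else "bend_low",
    )
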