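"""Sagittal joint angles from 2D skeleton keypoints.

Seven angles characterise a bend-and-reach posture, all in degrees:

======  =============================  ==========================================
angle   name                           definition
======  =============================  ==========================================
theta1  neck deviation                 neck→head vector vs the anti-gravity axis
theta2  upper-arm angle (L/R)          shoulder→elbow vs the trunk line
theta3  elbow included (L/R)           angle at the elbow; 180° = straight arm
theta4  trunk deviation                mid-hip→neck vs the anti-gravity axis
theta5  trunk–thigh included (L/R)     angle at the hip between trunk and thigh
theta6  thigh–calf included (L/R)      angle at the knee; 180° = straight leg
theta7  calf–ground inclination (L/R)  shank vs the horizontal
wrist   wrist deviation (L/R)          deviation of the hand from the forearm
                                       line (0° = straight); needs a hand point
======  =============================  ==========================================

Angles are computed as the arccosine of the normalised dot product of the two
defining vectors.  The anti-gravity axis is ``(0, -1)`` in image coordinates
(y down); the camera is assumed level.  Deviation angles (theta1, theta4,
theta7) reference that fixed axis and are therefore *not* rotation invariant;
included angles (theta2, theta3, theta5, theta6) are.

An angle is undefined (NaN) whenever a required keypoint is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .skeleton import MotionSequence, SkeletonFrame

__all__ = [
    "ANTI_GRAVITY",
    "JointAngleFrame",
    "JointAngleSeries",
    "AngleRangeSummary",
    "vector_angle",
    "head_point",
    "neck_flexion",
    "trunk_flexion",
    "upper_arm_angle",
    "elbow_included",
    "wrist_angle",
    "trunk_thigh",
    "thigh_calf",
    "calf_ground",
    "compute_angles",
    "angles_over_sequence",
    "angle_range_summary",
    "peak_angles",
]

#: "Up" in image coordinates (y increases downward).
ANTI_GRAVITY: tuple[float, float] = (0.0, -1.0)

_HORIZONTAL = (1.0, 0.0)


def vector_angle(u, v) -> float:
    """Angle between two 2D vectors in degrees, in [0, 180].

    The arccosine of the normalised dot product, evaluated in the
    numerically stable atan2(|cross|, dot) form (identical value, full
    precision near 0 and 180).  Returns NaN for a zero-length vector;
    symmetric in its arguments and invariant under positive scaling.
    """
    ux, uy = float(u[0]), float(u[1])
    vx, vy = float(v[0]), float(v[1])
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        return math.nan
    dot = ux * vx + uy * vy
    cross = ux * vy - uy * vx
    return math.degrees(math.atan2(abs(cross), dot))


def _vec(a, b) -> tuple[float, float] | None:
    if a is None or b is None:
        return None
    return (b.x - a.x, b.y - a.y)


def _angle(u, v) -> float:
    if u is None or v is None:
        return math.nan
    return vector_angle(u, v)


def head_point(frame: SkeletonFrame) -> tuple[float, float] | None:
    """Representative head point: midpoint of the ears, else the nose.

    The ears are the most rigid proxy for the top of the head available in
    the BODY_25 set.
    """
    re_, le = frame.get("REar"), frame.get("LEar")
    if re_ is not None and le is not None:
        return ((re_.x + le.x) / 2.0, (re_.y + le.y) / 2.0)
    nose = frame.get("Nose")
    if nose is not None:
        return (nose.x, nose.y)
    return None


def neck_flexion(frame: SkeletonFrame, up=ANTI_GRAVITY) -> float:
    """theta1: deviation of the neck→head vector from the anti-gravity axis."""
    neck = frame.get("Neck")
    head = head_point(frame)
    if neck is None or head is None:
        return math.nan
    return vector_angle((head[0] - neck.x, head[1] - neck.y), up)


def trunk_flexion(frame: SkeletonFrame, up=ANTI_GRAVITY) -> float:
    """theta4: deviation of the mid-hip→neck vector from the anti-gravity axis."""
    return _angle(_vec(frame.get("MidHip"), frame.get("Neck")), up)


def _side_label(side: str, part: str) -> str:
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    return f"{side}{part}"


def upper_arm_angle(frame: SkeletonFrame, side: str) -> float:
    """theta2: included angle between the upper arm and the trunk line.

    0° = arm hanging parallel to the trunk.
    """
    sh = frame.get(_side_label(side, "Shoulder"))
    el = frame.get(_side_label(side, "Elbow"))
    return _angle(_vec(sh, el), _vec(frame.get("Neck"), frame.get("MidHip")))


def elbow_included(frame: SkeletonFrame, side: str) -> float:
    """theta3: included angle at the elbow; 180° = straight arm."""
    sh = frame.get(_side_label(side, "Shoulder"))
    el = frame.get(_side_label(side, "Elbow"))
    wr = frame.get(_side_label(side, "Wrist"))
    return _angle(_vec(el, sh), _vec(el, wr))


def wrist_angle(frame: SkeletonFrame, side: str) -> float:
    """Wrist deviation from the straight forearm line: 180 - angle(wrist→elbow,
    wrist→hand).  Undefined without a hand point ("RHand"/"LHand")."""
    el = frame.get(_side_label(side, "Elbow"))
    wr = frame.get(_side_label(side, "Wrist"))
    hand = frame.get(_side_label(side, "Hand"))
    a = _angle(_vec(wr, el), _vec(wr, hand))
    return math.nan if math.isnan(a) else 180.0 - a


def trunk_thigh(frame: SkeletonFrame, side: str) -> float:
    """theta5: included angle at the hip between hip→neck and hip→knee."""
    hip = frame.get(_side_label(side, "Hip"))
    return _angle(_vec(hip, frame.get("Neck")), _vec(hip, frame.get(_side_label(side, "Knee"))))


def thigh_calf(frame: SkeletonFrame, side: str) -> float:
    """theta6: included angle at the knee; 180° = straight leg."""
    kn = frame.get(_side_label(side, "Knee"))
    hip = frame.get(_side_label(side, "Hip"))
    an = frame.get(_side_label(side, "Ankle"))
    return _angle(_vec(kn, hip), _vec(kn, an))


def calf_ground(frame: SkeletonFrame, side: str, folded: bool = True) -> float:
    """theta7: inclination of the shank to the horizontal.

    With ``folded=True`` (the default, used for REBA) the angle is folded into
    [0, 90]; ``folded=False`` returns the raw [0, 180] angle of knee→ankle
    against the +x axis.
    """
    kn = frame.get(_side_label(side, "Knee"))
    an = frame.get(_side_label(side, "Ankle"))
    a = _angle(_vec(kn, an), _HORIZONTAL)
    if math.isnan(a) or not folded:
        return a
    return 180.0 - a if a > 90.0 else a


_SIDED = ("theta2_upper_arm", "theta3_elbow", "theta5_trunk_thigh", "theta6_thigh_calf",
          "theta7_calf_ground", "wrist")


@dataclass(frozen=True)
class JointAngleFrame:
    """All sagittal joint angles for one frame, in degrees (NaN = undefined)."""

    frame_index: int
    theta1_neck: float = math.nan
    theta2_upper_arm_L: float = math.nan
    theta2_upper_arm_R: float = math.nan
    theta3_elbow_L: float = math.nan
    theta3_elbow_R: float = math.nan
    theta4_trunk: float = math.nan
    theta5_trunk_thigh_L: float = math.nan
    theta5_trunk_thigh_R: float = math.nan
    theta6_thigh_calf_L: float = math.nan
    theta6_thigh_calf_R: float = math.nan
    theta7_calf_ground_L: float = math.nan
    theta7_calf_ground_R: float = math.nan
    wrist_L: float = math.nan
    wrist_R: float = math.nan

    @classmethod
    def angle_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "frame_index"]

    def get(self, name: str, side: str | None = None) -> float:
        return getattr(self, f"{name}_{side}" if side else name)


def compute_angles(frame: SkeletonFrame, folded_theta7: bool = True) -> JointAngleFrame:
    """Compute every joint angle available in one skeleton frame."""
    return JointAngleFrame(
        frame_index=frame.frame_index,
        theta1_neck=neck_flexion(frame),
        theta2_upper_arm_L=upper_arm_angle(frame, "L"),
        theta2_upper_arm_R=upper_arm_angle(frame, "R"),
        theta3_elbow_L=elbow_included(frame, "L"),
        theta3_elbow_R=elbow_included(frame, "R"),
        theta4_trunk=trunk_flexion(frame),
        theta5_trunk_thigh_L=trunk_thigh(frame, "L"),
        theta5_trunk_thigh_R=trunk_thigh(frame, "R"),
        theta6_thigh_calf_L=thigh_calf(frame, "L"),
        theta6_thigh_calf_R=thigh_calf(frame, "R"),
        theta7_calf_ground_L=calf_ground(frame, "L", folded=folded_theta7),
        theta7_calf_ground_R=calf_ground(frame, "R", folded=folded_theta7),
        wrist_L=wrist_angle(frame, "L"),
        wrist_R=wrist_angle(frame, "R"),
    )


@dataclass
class JointAngleSeries:
    """Per-frame joint angles for a whole sequence."""

    frames: list[JointAngleFrame]
    fps: float
    smoothing: str = "none"

    def __len__(self) -> int:
        return len(self.frames)

    def to_frame(self) -> pd.DataFrame:
        """Angles as a DataFrame with frame index and time column."""
        names = JointAngleFrame.angle_names()
        data = {
            "frame": [f.frame_index for f in self.frames],
            "time_s": [f.frame_index / self.fps for f in self.frames],
        }
        for name in names:
            data[name] = [getattr(f, name) for f in self.frames]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, smoothing: str = "none") -> "JointAngleSeries":
        df = pd.read_csv(path)
        fps = 30.0
        if len(df) > 1 and df["time_s"].iloc[1] > 0:
            fps = round(1.0 / (df["time_s"].iloc[1] - df["time_s"].iloc[0]), 6)
        names = JointAngleFrame.angle_names()
        frames = [
            JointAngleFrame(frame_index=int(row["frame"]),
                            **{n: float(row[n]) for n in names if n in df.columns})
            for _, row in df.iterrows()
        ]
        return cls(frames, fps=fps, smoothing=smoothing)


def _nan_moving_median(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving median ignoring NaNs; a NaN input stays NaN."""
    if window <= 1:
        return values.copy()
    half = window // 2
    out = values.copy()
    n = len(values)
    for i in range(n):
        if math.isnan(values[i]):
            continue  # do not invent values where the raw angle is undefined
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = values[lo:hi]
        win = win[~np.isnan(win)]
        out[i] = float(np.median(win))
    return out


def angles_over_sequence(
    seq: MotionSequence,
    smoothing_window: int = 5,
    folded_theta7: bool = True,
) -> JointAngleSeries:
    """Per-frame joint angles with optional centered moving-median smoothing.

    The median window (default 5 frames at 30 fps) suppresses single-frame
    keypoint jitter; undefined values are excluded from each window and a
    window of 1 returns the raw per-frame angles.
    """
    if not seq.frames:
        raise ValueError("empty sequence")
    raw = [compute_angles(fr, folded_theta7=folded_theta7) for fr in seq]
    if smoothing_window <= 1:
        return JointAngleSeries(raw, fps=seq.fps, smoothing="none")
    names = JointAngleFrame.angle_names()
    cols = {n: _nan_moving_median(np.array([getattr(f, n) for f in raw], dtype=float),
                                  smoothing_window)
            for n in names}
    smoothed = [
        JointAngleFrame(frame_index=f.frame_index, **{n: float(cols[n][i]) for n in names})
        for i, f in enumerate(raw)
    ]
    return JointAngleSeries(smoothed, fps=seq.fps,
                            smoothing=f"moving_median(window={smoothing_window})")


@dataclass
class AngleRangeSummary:
    """Min/max of every defined angle over a series (or a frame range)."""

    task: str
    ranges: dict[str, tuple[float, float]]  # angle name -> (min, max), degrees

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.task, name, lo, hi) for name, (lo, hi) in self.ranges.items()]
        return pd.DataFrame(rows, columns=["task", "angle", "min_deg", "max_deg"])


def _subset(series: JointAngleSeries, frame_range: tuple[int, int] | None) -> list[JointAngleFrame]:
    if frame_range is None:
        return series.frames
    lo, hi = frame_range
    sel = [f for f in series.frames if lo <= f.frame_index <= hi]
    if not sel:
        raise ValueError(f"frame range {frame_range} selects no frames")
    return sel


def angle_range_summary(
    series: JointAngleSeries, task: str = "", frame_range: tuple[int, int] | None = None
) -> AngleRangeSummary:
    """Min and max per angle, skipping undefined values."""
    frames = _subset(series, frame_range)
    ranges = {}
    for name in JointAngleFrame.angle_names():
        vals = [getattr(f, name) for f in frames]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            ranges[name] = (min(vals), max(vals))
    return AngleRangeSummary(task=task, ranges=ranges)


def peak_angles(series: JointAngleSeries, frame_range: tuple[int, int] | None = None) -> dict[str, float]:
    """Maximum of each defined angle within a frame range (inclusive)."""
    frames = _subset(series, frame_range)
    peaks = {}
    for name in JointAngleFrame.angle_names():
        vals = [getattr(f, name) for f in frames]
        vals = [v for v in vals if not math.isnan(v)]
        if vals:
            peaks[name] = max(vals)
    return peaks
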