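"""Rapid Entire Body Assessment (REBA) scoring engine.

REBA grades whole-body postural load on a 1–15 scale.  Body parts are split
into Group A (trunk, neck, legs) and Group B (upper arm, forearm, wrist).
Each part receives an integer sub-score from its joint angle plus adjustment
flags; the published Table A and Table B matrices combine each group, load /
coupling and muscle-use points are added to give Score A and Score B, and
Table C combines those into Score C.  An activity score (0–3: static posture
held over a minute, more than four repetitions per minute, rapid or unstable
posture change — one point each) is added for the total, which maps to one of
five action levels / risk labels.

The matrices below are the standard published REBA tables (Hignett &
McAtamney).  Load and muscle-use points are additive to *both* group scores,
matching this scoring variant's worksheet layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .kinematics import JointAngleFrame, JointAngleSeries

__all__ = [
    "TABLE_A",
    "TABLE_B",
    "TABLE_C",
    "RiskLevel",
    "Stance",
    "GroupAInputs",
    "GroupBInputs",
    "RebaConfig",
    "RebaSheet",
    "RiskCurve",
    "score_trunk",
    "score_neck",
    "score_legs",
    "score_upper_arm",
    "score_forearm",
    "score_wrist",
    "load_score_from_kg",
    "table_a",
    "table_b",
    "table_c",
    "score_A",
    "score_B",
    "activity_score",
    "risk_level",
    "assemble_sheet",
    "score_frame",
    "score_sequence",
]

# Table A: trunk 1-5 (axis 0), neck 1-3 (axis 1), legs 1-4 (axis 2).
TABLE_A = np.array([
    # neck 1          neck 2          neck 3
    [[1, 2, 3, 4], [1, 2, 3, 4], [3, 3, 5, 6]],   # trunk 1
    [[2, 3, 4, 5], [3, 4, 5, 6], [4, 5, 6, 7]],   # trunk 2
    [[2, 4, 5, 6], [4, 5, 6, 7], [5, 6, 7, 8]],   # trunk 3
    [[3, 5, 6, 7], [5, 6, 7, 8], [6, 7, 8, 9]],   # trunk 4
    [[4, 6, 7, 8], [6, 7, 8, 9], [7, 8, 9, 9]],   # trunk 5
], dtype=int)

# Table B: upper arm 1-6 (axis 0), forearm 1-2 (axis 1), wrist 1-3 (axis 2).
TABLE_B = np.array([
    # forearm 1     forearm 2
    [[1, 2, 2], [1, 2, 3]],   # upper arm 1
    [[1, 2, 3], [2, 3, 4]],   # upper arm 2
    [[3, 4, 5], [4, 5, 5]],   # upper arm 3
    [[4, 5, 5], [5, 6, 7]],   # upper arm 4
    [[6, 7, 8], [7, 8, 8]],   # upper arm 5
    [[7, 8, 8], [8, 9, 9]],   # upper arm 6
], dtype=int)

# Table C: score A 1-12 (rows), score B 1-12 (columns).
TABLE_C = np.array([
    [1, 1, 1, 2, 3, 3, 4, 5, 6, 7, 7, 7],
    [1, 2, 2, 3, 4, 4, 5, 6, 6, 7, 7, 8],
    [2, 3, 3, 3, 4, 5, 6, 7, 7, 8, 8, 8],
    [3, 4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9],
    [4, 4, 4, 5, 6, 7, 8, 8, 9, 9, 9, 9],
    [6, 6, 6, 7, 8, 8, 9, 9, 10, 10, 10, 10],
    [7, 7, 7, 8, 9, 9, 9, 10, 10, 11, 11, 11],
    [8, 8, 8, 9, 10, 10, 10, 10, 10, 11, 11, 11],
    [9, 9, 9, 10, 10, 10, 11, 11, 11, 12, 12, 12],
    [10, 10, 10, 11, 11, 11, 11, 12, 12, 12, 12, 12],
    [11, 11, 11, 11, 12, 12, 12, 12, 12, 12, 12, 12],
    [12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12, 12],
], dtype=int)


class RiskLevel(str, Enum):
    NEGLIGIBLE = "negligible"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


class Stance(str, Enum):
    BILATERAL = "bilateral"
    UNILATERAL_OR_UNSTABLE = "unilateral_or_unstable"
    SITTING = "sitting"
    WALKING = "walking"


def _check_range(name: str, value: int, lo: int, hi: int) -> int:
    if not isinstance(value, (int, np.integer)) or not (lo <= value <= hi):
        raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")
    return int(value)


@dataclass(frozen=True)
class GroupAInputs:
    """Sub-scores and adjustments feeding Score A (trunk, neck, legs)."""

    trunk_score: int
    neck_score: int
    legs_score: int
    load_score: int = 0
    muscle_use: int = 0

    def __post_init__(self) -> None:
        _check_range("trunk_score", self.trunk_score, 1, 5)
        _check_range("neck_score", self.neck_score, 1, 3)
        _check_range("legs_score", self.legs_score, 1, 4)
        _check_range("load_score", self.load_score, 0, 3)
        _check_range("muscle_use", self.muscle_use, 0, 1)


@dataclass(frozen=True)
class GroupBInputs:
    """Sub-scores and adjustments feeding Score B (upper arm, forearm, wrist)."""

    upper_arm_score: int
    forearm_score: int
    wrist_score: int
    coupling_load_score: int = 0
    muscle_use: int = 0

    def __post_init__(self) -> None:
        _check_range("upper_arm_score", self.upper_arm_score, 1, 6)
        _check_range("forearm_score", self.forearm_score, 1, 3)
        _check_range("wrist_score", self.wrist_score, 1, 3)
        _check_range("coupling_load_score", self.coupling_load_score, 0, 3)
        _check_range("muscle_use", self.muscle_use, 0, 1)


# ---------------------------------------------------------------------------
# angle -> sub-score rules


def score_trunk(angle_dev: float, twist: bool = False, side_bend: bool = False,
                upright_tol: float = 5.0) -> int:
    """Trunk sub-score (1-5) from the trunk deviation angle.

    1 within ``upright_tol`` of upright, 2 up to 20°, 3 up to 60°, 4 beyond;
    +1 for twist or side-bend, capped at 5.  The upright tolerance absorbs
    keypoint jitter that would otherwise never score an upright trunk as 1.
    """
    d = abs(angle_dev)
    if d <= upright_tol:
        base = 1
    elif d <= 20.0:
        base = 2
    elif d <= 60.0:
        base = 3
    else:
        base = 4
    if twist or side_bend:
        base += 1
    return min(base, 5)


def score_neck(angle: float, extension: bool = False, twist_or_side: bool = False) -> int:
    """Neck sub-score (1-3): 1 for flexion up to 20°, 2 beyond (or extension),
    +1 for twist/side-bend, capped at 3."""
    base = 2 if (angle > 20.0 or extension) else 1
    if twist_or_side:
        base += 1
    return min(base, 3)


def score_legs(stance: Stance | str, knee_included: float = 180.0) -> int:
    """Leg sub-score (1-4) from stance and the knee (thigh-calf) included angle.

    Base 1 for bilateral stance, walking or sitting; 2 for unilateral or
    unstable stance.  +1 when the knee included angle is in [120, 150]
    (moderate flexion), +2 when below 120 (deep flexion; not applied when
    sitting).  Capped at 4.
    """
    stance = Stance(stance)
    base = 2 if stance is Stance.UNILATERAL_OR_UNSTABLE else 1
    if stance is not Stance.SITTING:
        if knee_included < 120.0:
            base += 2
        elif knee_included <= 150.0:
            base += 1
    return min(base, 4)


def score_upper_arm(angle: float, abducted_or_rotated: bool = False,
                    shoulder_raised: bool = False, supported: bool = False) -> int:
    """Upper-arm sub-score (1-6) from the arm-trunk included angle.

    Base 1 up to 20°, 2 to 45°, 3 to 90°, 4 beyond 90°; +1 each for
    abduction/rotation and a raised shoulder, -1 when the arm is externally
    supported; clamped to [1, 6].
    """
    if angle <= 20.0:
        base = 1
    elif angle <= 45.0:
        base = 2
    elif angle <= 90.0:
        base = 3
    else:
        base = 4
    base += int(abducted_or_rotated) + int(shoulder_raised) - int(supported)
    return max(1, min(base, 6))


def score_forearm(flexion: float) -> int:
    """Forearm sub-score (1-2): 1 inside the 60-100° elbow flexion window,
    2 outside it.  ``flexion`` is 180° minus the elbow included angle."""
    return 1 if 60.0 <= flexion <= 100.0 else 2


def score_wrist(angle: float | None, deviated_or_twisted: bool = False,
                default: int = 1) -> int:
    """Wrist sub-score (1-3): 1 within 15° of straight, 2 beyond; +1 for
    deviation/twist; capped at 3.  When the wrist angle is unavailable the
    configured default applies (wrists are near-static in lifting tasks)."""
    if angle is None or (isinstance(angle, float) and math.isnan(angle)):
        base = _check_range("default wrist score", default, 1, 3)
    else:
        base = 1 if angle <= 15.0 else 2
    if deviated_or_twisted:
        base += 1
    return min(base, 3)


def load_score_from_kg(load_kg: float, shock: bool = False) -> int:
    """Map a handled load to the 0-2(+1) load/force score: <5 kg → 0,
    5-10 kg → 1, >10 kg → 2; +1 for shock or rapid force build-up."""
    if load_kg < 5.0:
        s = 0
    elif load_kg <= 10.0:
        s = 1
    else:
        s = 2
    return s + int(shock)


# ---------------------------------------------------------------------------
# matrix lookups and assembly


def table_a(trunk: int, neck: int, legs: int) -> int:
    """Group A matrix lookup (1-9)."""
    return int(TABLE_A[_check_range("trunk", trunk, 1, 5) - 1,
                       _check_range("neck", neck, 1, 3) - 1,
                       _check_range("legs", legs, 1, 4) - 1])


def table_b(upper_arm: int, forearm: int, wrist: int) -> int:
    """Group B matrix lookup (1-9)."""
    return int(TABLE_B[_check_range("upper_arm", upper_arm, 1, 6) - 1,
                       _check_range("forearm", forearm, 1, 2) - 1,
                       _check_range("wrist", wrist, 1, 3) - 1])


def table_c(score_a: int, score_b: int) -> int:
    """Score C matrix lookup (1-12); inputs above 12 are clamped to 12."""
    if score_a < 1 or score_b < 1:
        raise ValueError("table C inputs must be >= 1")
    return int(TABLE_C[min(score_a, 12) - 1, min(score_b, 12) - 1])


def score_A(inputs: GroupAInputs) -> int:
    """Score A = Table A lookup + load + muscle-use."""
    return table_a(inputs.trunk_score, inputs.neck_score, inputs.legs_score) \
        + inputs.load_score + inputs.muscle_use


def score_B(inputs: GroupBInputs) -> int:
    """Score B = Table B lookup + coupling/load + muscle-use."""
    # forearm sub-score 3 can arise from the in/out-movement adjustment;
    # the matrix itself has two forearm rows, so clamp for the lookup.
    return table_b(inputs.upper_arm_score, min(inputs.forearm_score, 2),
                   inputs.wrist_score) + inputs.coupling_load_score + inputs.muscle_use


def activity_score(static_over_1min: bool = False, repeated_over_4_per_min: bool = False,
                   rapid_large_change: bool = False) -> int:
    """Activity score 0-3: one point per activity category present."""
    return int(static_over_1min) + int(repeated_over_4_per_min) + int(rapid_large_change)


_RISK_BANDS = (
    (1, 1, 0, RiskLevel.NEGLIGIBLE),
    (2, 3, 1, RiskLevel.LOW),
    (4, 7, 2, RiskLevel.MEDIUM),
    (8, 10, 3, RiskLevel.HIGH),
    (11, 15, 4, RiskLevel.VERY_HIGH),
)


def risk_level(total: int) -> tuple[int, RiskLevel]:
    """Map a total REBA score (1-15) to (action level 0-4, risk label)."""
    for lo, hi, level, label in _RISK_BANDS:
        if lo <= total <= hi:
            return level, label
    raise ValueError(f"total REBA score must be in [1, 15], got {total!r}")


@dataclass(frozen=True)
class RebaSheet:
    """One posture's complete REBA worksheet."""

    group_a: GroupAInputs
    group_b: GroupBInputs
    score_a: int
    score_b: int
    score_c: int
    activity: int
    total: int
    action_level: int
    risk: RiskLevel
    side: str | None = None  # side scored when derived from angles

    def as_dict(self) -> dict:
        return {
            "trunk": self.group_a.trunk_score, "neck": self.group_a.neck_score,
            "legs": self.group_a.legs_score, "load_a": self.group_a.load_score,
            "muscle_use_a": self.group_a.muscle_use,
            "upper_arm": self.group_b.upper_arm_score, "forearm": self.group_b.forearm_score,
            "wrist": self.group_b.wrist_score, "load_b": self.group_b.coupling_load_score,
            "muscle_use_b": self.group_b.muscle_use,
            "score_a": self.score_a, "score_b": self.score_b, "score_c": self.score_c,
            "activity": self.activity, "total": self.total,
            "action_level": self.action_level, "risk": self.risk.value,
            "side": self.side,
        }


def assemble_sheet(group_a: GroupAInputs, group_b: GroupBInputs, activity: int = 0,
                   side: str | None = None) -> RebaSheet:
    """Combine group inputs and the activity score into a full REBA sheet."""
    _check_range("activity", activity, 0, 3)
    a = score_A(group_a)
    b = score_B(group_b)
    c = table_c(a, b)
    total = min(c + activity, 15)
    level, label = risk_level(total)
    return RebaSheet(group_a, group_b, a, b, c, activity, total, level, label, side)


# ---------------------------------------------------------------------------
# scoring from joint angles


@dataclass(frozen=True)
class RebaConfig:
    """Scoring configuration: load, coupling, muscle use, posture flags.

    Flags that cannot be measured from sagittal 2D keypoints (twist,
    side-bend, abduction) are supplied here and default to off, matching a
    protocol whose pre-input variables are set to zero.
    """

    load_kg: float = 0.0
    load_score: int | None = None       # explicit override of load_kg mapping
    shock: bool = False
    coupling_score: int = 0             # 0 good .. 3 unacceptable grip
    muscle_use_a: int = 0
    muscle_use_b: int = 0
    trunk_twist: bool = False
    trunk_side_bend: bool = False
    neck_twist_or_side: bool = False
    neck_extension: bool = False
    wrist_deviated: bool = False
    shoulder_raised: bool = False
    arm_abducted: bool = False
    arm_supported: bool = False
    stance: Stance = Stance.BILATERAL
    static_over_1min: bool = False
    repeated_over_4_per_min: bool = False
    rapid_large_change: bool = False
    side_policy: str = "max"            # max | left | right
    default_wrist_score: int = 1
    trunk_upright_tol_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.side_policy not in ("max", "left", "right"):
            raise ValueError("side_policy must be 'max', 'left' or 'right'")
        object.__setattr__(self, "stance", Stance(self.stance))

    def effective_load_score(self) -> int:
        if self.load_score is not None:
            return _check_range("load_score", self.load_score, 0, 3)
        return min(load_score_from_kg(self.load_kg, self.shock), 3)

    def activity(self) -> int:
        return activity_score(self.static_over_1min, self.repeated_over_4_per_min,
                              self.rapid_large_change)

    @classmethod
    def from_dict(cls, d: dict) -> "RebaConfig":
        return cls(**d)


def _score_side(angles: JointAngleFrame, config: RebaConfig, side: str) -> RebaSheet | None:
    trunk = angles.theta4_trunk
    neck = angles.theta1_neck
    knee = angles.get("theta6_thigh_calf", side)
    ua = angles.get("theta2_upper_arm", side)
    elbow = angles.get("theta3_elbow", side)
    if any(math.isnan(v) for v in (trunk, neck, knee, ua, elbow)):
        return None
    wrist = angles.get("wrist", side)
    ga = GroupAInputs(
        trunk_score=score_trunk(trunk, config.trunk_twist, config.trunk_side_bend,
                                config.trunk_upright_tol_deg),
        neck_score=score_neck(neck, config.neck_extension, config.neck_twist_or_side),
        legs_score=score_legs(config.stance, knee),
        load_score=config.effective_load_score(),
        muscle_use=config.muscle_use_a,
    )
    gb = GroupBInputs(
        upper_arm_score=score_upper_arm(ua, config.arm_abducted, config.shoulder_raised,
                                        config.arm_supported),
        forearm_score=score_forearm(180.0 - elbow),
        wrist_score=score_wrist(wrist, config.wrist_deviated, config.default_wrist_score),
        coupling_load_score=config.coupling_score,
        muscle_use=config.muscle_use_b,
    )
    return assemble_sheet(ga, gb, config.activity(), side=side)


def score_frame(angles: JointAngleFrame, config: RebaConfig | None = None) -> RebaSheet | None:
    """Score one frame's joint angles; None when required angles are undefined.

    ``side_policy="max"`` scores both sides and keeps the higher total (ties
    keep the left side, the first scored).
    """
    config = config or RebaConfig()
    if config.side_policy == "left":
        return _score_side(angles, config, "L")
    if config.side_policy == "right":
        return _score_side(angles, config, "R")
    left = _score_side(angles, config, "L")
    right = _score_side(angles, config, "R")
    if left is None:
        return right
    if right is None:
        return left
    return left if left.total >= right.total else right


@dataclass
class RiskCurve:
    """Per-frame REBA totals and risk levels for a sequence."""

    sheets: list[RebaSheet | None]  # None = unscorable frame
    frame_indices: list[int]
    fps: float

    def __len__(self) -> int:
        return len(self.sheets)

    @property
    def totals(self) -> list[int | None]:
        return [s.total if s else None for s in self.sheets]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx, sheet in zip(self.frame_indices, self.sheets):
            if sheet is None:
                rows.append({"frame": idx, "time_s": idx / self.fps, "scorable": False})
            else:
                rows.append({"frame": idx, "time_s": idx / self.fps, "scorable": True,
                             "score_a": sheet.score_a, "score_b": sheet.score_b,
                             "score_c": sheet.score_c, "activity": sheet.activity,
                             "total": sheet.total, "action_level": sheet.action_level,
                             "risk": sheet.risk.value})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def score_sequence(series: JointAngleSeries, config: RebaConfig | None = None) -> RiskCurve:
    """Score every frame of a joint-angle series; unscorable frames are
    flagged (None), never dropped."""
    config = config or RebaConfig()
    sheets = [score_frame(f, config) for f in series.frames]
    return RiskCurve(sheets, [f.frame_index for f in series.frames], series.fps)
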