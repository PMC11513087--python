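"""Core data model: 2D keypoints, skeleton frames, motion sequences.

Coordinates follow the image convention of the pose-estimator JSON dialect:
origin at the top-left corner, x to the right, y *downward*.  All downstream
geometry (the anti-gravity vector in particular) is stated in this convention.

A keypoint with confidence 0 is *missing*: its x and y carry no meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

__all__ = [
    "BODY_25_LABELS",
    "EXTENDED_LABELS",
    "ACCEPTED_LABELS",
    "Keypoint2D",
    "SkeletonFrame",
    "MotionSequence",
    "SubjectInfo",
]

#: The 25 body landmarks of the BODY_25 keypoint set, in estimator index order.
BODY_25_LABELS: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

#: Optional extra landmarks (a single representative hand point per side,
#: used for the wrist deviation angle; BODY_25 itself carries no hand point).
EXTENDED_LABELS: tuple[str, ...] = ("RHand", "LHand")

ACCEPTED_LABELS: frozenset[str] = frozenset(BODY_25_LABELS) | frozenset(EXTENDED_LABELS)


@dataclass(frozen=True)
class Keypoint2D:
    """One named landmark in one frame: pixel position plus detector confidence."""

    name: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.name not in ACCEPTED_LABELS:
            raise ValueError(
                f"unknown keypoint label {self.name!r}; accepted labels are: "
                + ", ".join(sorted(ACCEPTED_LABELS))
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence must be in [0, 1], got {self.confidence!r} for {self.name!r}"
            )

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0

    def as_missing(self) -> "Keypoint2D":
        return Keypoint2D(self.name, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SkeletonFrame:
    """All keypoints detected in one video frame."""

    frame_index: int
    timestamp: float
    keypoints: dict[str, Keypoint2D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        for label, kp in self.keypoints.items():
            if label != kp.name:
                raise ValueError(f"keypoint {kp.name!r} stored under label {label!r}")

    def get(self, label: str) -> Keypoint2D | None:
        """Return the keypoint if present (confidence > 0), else None."""
        kp = self.keypoints.get(label)
        if kp is None or kp.missing:
            return None
        return kp

    def present_labels(self) -> list[str]:
        return [l for l, kp in self.keypoints.items() if not kp.missing]

    @classmethod
    def all_missing(cls, frame_index: int, timestamp: float) -> "SkeletonFrame":
        kps = {l: Keypoint2D(l, 0.0, 0.0, 0.0) for l in BODY_25_LABELS}
        return cls(frame_index, timestamp, kps)


@dataclass(frozen=True)
class SubjectInfo:
    """Optional metadata about the filmed subject."""

    id: str | None = None
    sex: str | None = None
    stature_m: float | None = None
    mass_kg: float | None = None


@dataclass
class MotionSequence:
    """An ordered sequence of skeleton frames — the unit of analysis.

    Frame indices must be strictly increasing and timestamps consistent with
    ``frame_index / fps`` to within 1 microsecond.
    """

    frames: list[SkeletonFrame]
    fps: float = 30.0
    subject: SubjectInfo = field(default_factory=SubjectInfo)
    task: str = ""

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        prev = -1
        for fr in self.frames:
            if fr.frame_index <= prev:
                raise ValueError("frame_index must be strictly increasing")
            prev = fr.frame_index
            if abs(fr.timestamp - fr.frame_index / self.fps) > 1e-6:
                raise ValueError(
                    f"timestamp {fr.timestamp} inconsistent with frame_index "
                    f"{fr.frame_index} at {self.fps} fps"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    def with_frames(self, frames: list[SkeletonFrame]) -> "MotionSequence":
        return MotionSequence(frames, fps=self.fps, subject=self.subject, task=self.task)


def _replace_keypoints(frame: SkeletonFrame, keypoints: dict[str, Keypoint2D]) -> SkeletonFrame:
    return replace(frame, keypoints=keypoints)
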