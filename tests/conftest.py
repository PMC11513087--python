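import json

import pytest

from rebakit.skeleton import BODY_25_LABELS, Keypoint2D, SkeletonFrame
from rebakit.synthetic import BodyModel


@pytest.fixture
def body():
    """Proportional body at the study cohort's mean stature."""
    return BodyModel.from_stature(1.64)


def make_frame(points: dict[str, tuple[float, float]], frame_index: int = 0,
               confidence: float = 1.0) -> SkeletonFrame:
    """Build a frame from label -> (x, y); everything else is absent."""
    kps = {label: Keypoint2D(label, x, y, confidence) for label, (x, y) in points.items()}
    return SkeletonFrame(frame_index, frame_index / 30.0, kps)


def write_pose_json(path, people_triplets: list[list[float]]) -> None:
    """Write one pose JSON frame file from flat keypoint triplet lists."""
    doc = {"version": 1.3, "people": [{"pose_keypoints_2d": t} for t in people_triplets]}
    path.write_text(json.dumps(doc))


def flat_triplets(base_conf: float = 0.9) -> list[float]:
    """One person's 25 keypoint triplets with distinct coordinates."""
    out = []
    for i in range(len(BODY_25_LABELS)):
        out += [10.0 * i, 5.0 * i + 1.0, base_conf]
    return out
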