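"""Read, validate, clean and write 2D keypoint sequences.

Two on-disk formats are supported:

* the pose-estimator JSON dialect — one JSON file per frame, with
  ``people[].pose_keypoints_2d`` as a flat ``[x, y, c] * 25`` array in
  BODY_25 index order;
* a plain keypoint CSV with columns ``frame,label,x,y,confidence``.

Cleaning utilities mark low-confidence keypoints missing and fill short
occlusion gaps by linear interpolation.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from .skeleton import (
    ACCEPTED_LABELS,
    BODY_25_LABELS,
    Keypoint2D,
    MotionSequence,
    SkeletonFrame,
    SubjectInfo,
)

__all__ = [
    "read_pose_json_dir",
    "write_pose_json_dir",
    "read_keypoint_csv",
    "write_keypoint_csv",
    "filter_confidence",
    "interpolate_gaps",
]

CSV_COLUMNS = ("frame", "label", "x", "y", "confidence")

_INDEX_RE = re.compile(r"(\d+)")


def _frame_sort_key(path: Path) -> tuple:
    """Order frame files by the last integer in the stem (estimator naming),
    falling back to lexicographic order."""
    nums = _INDEX_RE.findall(path.stem)
    return (0, int(nums[-1]), path.name) if nums else (1, 0, path.name)


def _person_triplets(person: dict) -> list[float]:
    flat = person.get("pose_keypoints_2d", [])
    if len(flat) != 3 * len(BODY_25_LABELS):
        raise ValueError(
            f"pose_keypoints_2d must hold {3 * len(BODY_25_LABELS)} values, got {len(flat)}"
        )
    return [float(v) for v in flat]


def _best_person(people: list[dict]) -> list[float] | None:
    """Highest summed confidence wins; ties keep the first-listed person."""
    best, best_sum = None, -1.0
    for person in people:
        flat = _person_triplets(person)
        total = sum(flat[2::3])
        if total > best_sum:
            best, best_sum = flat, total
    return best


def read_pose_json_dir(path: str | Path, fps: float = 30.0, pattern: str = "*.json") -> MotionSequence:
    """Read a directory of per-frame pose JSON files into a MotionSequence.

    Frames are ordered by the integer index embedded in each filename.  In
    multi-person frames the person with the highest summed confidence is
    retained; frames with an empty ``people`` list become all-missing frames.
    """
    path = Path(path)
    files = sorted(path.glob(pattern), key=_frame_sort_key)
    if not files:
        raise ValueError(f"no pose JSON files matching {pattern!r} in {path}")
    frames: list[SkeletonFrame] = []
    for i, f in enumerate(files):
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed pose JSON in {f.name}: {exc}") from exc
        flat = _best_person(doc.get("people", []))
        if flat is None:
            frames.append(SkeletonFrame.all_missing(i, i / fps))
            continue
        kps = {}
        for j, label in enumerate(BODY_25_LABELS):
            x, y, c = flat[3 * j : 3 * j + 3]
            if c == 0.0:
                x = y = 0.0
            kps[label] = Keypoint2D(label, x, y, c)
        frames.append(SkeletonFrame(i, i / fps, kps))
    return MotionSequence(frames, fps=fps)


def write_pose_json_dir(seq: MotionSequence, path: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a sequence as per-frame pose JSON files (inverse of the reader)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, frame in enumerate(seq):
        flat: list[float] = []
        for label in BODY_25_LABELS:
            kp = frame.keypoints.get(label)
            if kp is None or kp.missing:
                flat += [0.0, 0.0, 0.0]
            else:
                flat += [kp.x, kp.y, kp.confidence]
        doc = {"version": 1.3, "people": [{"pose_keypoints_2d": flat}]}
        out = path / f"{prefix}_{i:012d}_keypoints.json"
        out.write_text(json.dumps(doc))
        written.append(out)
    return written


def read_keypoint_csv(path: str | Path, fps: float = 30.0) -> MotionSequence:
    """Read a plain keypoint table (columns frame,label,x,y,confidence)."""
    df = pd.read_csv(path)
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"keypoint CSV is missing columns: {sorted(missing_cols)}")
    bad = sorted(set(df["label"]) - ACCEPTED_LABELS)
    if bad:
        raise ValueError(
            f"unknown keypoint labels {bad}; accepted labels are: "
            + ", ".join(sorted(ACCEPTED_LABELS))
        )
    frames = []
    for idx, group in df.groupby("frame", sort=True):
        kps = {}
        for row in group.itertuples(index=False):
            kps[row.label] = Keypoint2D(row.label, float(row.x), float(row.y), float(row.confidence))
        idx = int(idx)
        frames.append(SkeletonFrame(idx, idx / fps, kps))
    if not frames:
        raise ValueError(f"no keypoint rows in {path}")
    return MotionSequence(frames, fps=fps)


def write_keypoint_csv(seq: MotionSequence, path: str | Path) -> None:
    """Write a sequence to keypoint CSV; round-trips losslessly with the reader."""
    rows = []
    for frame in seq:
        for label, kp in frame.keypoints.items():
            rows.append((frame.frame_index, label, kp.x, kp.y, kp.confidence))
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)


def filter_confidence(seq: MotionSequence, threshold: float) -> MotionSequence:
    """Mark keypoints with confidence below ``threshold`` as missing.

    Idempotent at a fixed threshold; the frame count never changes.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    frames = []
    for frame in seq:
        kps = {
            label: (kp.as_missing() if kp.confidence < threshold else kp)
            for label, kp in frame.keypoints.items()
        }
        frames.append(SkeletonFrame(frame.frame_index, frame.timestamp, kps))
    return seq.with_frames(frames)


def interpolate_gaps(seq: MotionSequence, max_gap_frames: int = 5) -> MotionSequence:
    """Fill short missing runs per keypoint label by linear interpolation.

    A run of at most ``max_gap_frames`` consecutive missing frames flanked on
    both sides by present frames is filled linearly in x and y; the filled
    confidence is the minimum of the two flanking confidences.  Longer runs
    and runs touching the sequence boundary stay missing.  Originally present
    keypoints are never altered.
    """
    n = len(seq.frames)
    # label -> per-frame replacement keypoints
    fills: dict[int, dict[str, Keypoint2D]] = {i: {} for i in range(n)}
    labels = {label for fr in seq for label in fr.keypoints}
    for label in labels:
        kps = [fr.keypoints.get(label) for fr in seq.frames]
        present = [i for i, kp in enumerate(kps) if kp is not None and not kp.missing]
        for a, b in zip(present, present[1:]):
            gap = b - a - 1
            if gap == 0 or gap > max_gap_frames:
                continue
            ka, kb = kps[a], kps[b]
            conf = min(ka.confidence, kb.confidence)
            for i in range(a + 1, b):
                t = (i - a) / (b - a)
                fills[i][label] = Keypoint2D(
                    label, ka.x + t * (kb.x - ka.x), ka.y + t * (kb.y - ka.y), conf
                )
    frames = []
    for i, frame in enumerate(seq):
        if not fills[i]:
            frames.append(frame)
            continue
        kps = dict(frame.keypoints)
        kps.update(fills[i])
        frames.append(SkeletonFrame(frame.frame_index, frame.timestamp, kps))
    return seq.with_frames(frames)
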