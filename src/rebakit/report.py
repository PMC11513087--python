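"""Assessment report assembly: phases, peak angles, representative postures.

A report summarises one analysed sequence: per behaviour phase it carries the
peak joint angles, the representative REBA sheet (the frame with the maximum
total inside the phase — the conservative choice), comfort grades for neck,
trunk and knee at their phase peaks, and flags every phase whose action level
reaches 3 (total >= 8).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .comfort import ComfortGrade, GradientThresholds, classify_comfort, default_thresholds
from .kinematics import JointAngleSeries, peak_angles
from .reba import RebaConfig, RebaSheet, RiskCurve, score_sequence
from .skeleton import SubjectInfo

__all__ = ["PhaseAnnotation", "PhaseResult", "AssessmentReport",
           "read_annotations_csv", "build_report"]

HIGH_RISK_ACTION_LEVEL = 3


@dataclass(frozen=True)
class PhaseAnnotation:
    """Named, non-overlapping frame ranges partitioning a task."""

    task: str
    phases: tuple[tuple[str, int, int], ...]  # (name, start_frame, end_frame) inclusive

    def __post_init__(self) -> None:
        spans = sorted((s, e, n) for n, s, e in self.phases)
        for s, e, n in spans:
            if s > e or s < 0:
                raise ValueError(f"phase {n!r}: invalid range [{s}, {e}]")
        for (s0, e0, n0), (s1, e1, n1) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ValueError(f"phases {n0!r} and {n1!r} overlap")


def read_annotations_csv(path) -> PhaseAnnotation:
    """Read an annotation CSV with columns task,phase,start_frame,end_frame."""
    df = pd.read_csv(path)
    needed = {"task", "phase", "start_frame", "end_frame"}
    if missing := needed - set(df.columns):
        raise ValueError(f"annotation CSV is missing columns: {sorted(missing)}")
    task = str(df["task"].iloc[0]) if len(df) else ""
    phases = tuple(
        (str(r.phase), int(r.start_frame), int(r.end_frame))
        for r in df.itertuples(index=False)
    )
    return PhaseAnnotation(task=task, phases=phases)


@dataclass
class PhaseResult:
    name: str
    start_frame: int
    end_frame: int
    peak_angles: dict[str, float]
    representative: RebaSheet | None
    representative_frame: int | None
    comfort: dict[str, str]
    flagged_high_risk: bool


@dataclass
class AssessmentReport:
    subject: SubjectInfo
    task: str
    n_frames: int
    n_unscorable: int
    phases: list[PhaseResult]
    flagged_phases: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.flagged_phases = [p.name for p in self.phases if p.flagged_high_risk]

    def as_dict(self) -> dict:
        return {
            "subject": vars(self.subject),
            "task": self.task,
            "n_frames": self.n_frames,
            "n_unscorable": self.n_unscorable,
            "phases": [
                {
                    "name": p.name,
                    "frames": [p.start_frame, p.end_frame],
                    "peak_angles_deg": {k: round(v, 3) for k, v in p.peak_angles.items()},
                    "reba": p.representative.as_dict() if p.representative else None,
                    "reba_frame": p.representative_frame,
                    "comfort": p.comfort,
                    "flagged_high_risk": p.flagged_high_risk,
                }
                for p in self.phases
            ],
            "flagged_phases": self.flagged_phases,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [f"Task: {self.task or '(unlabelled)'}",
                 f"Frames: {self.n_frames} ({self.n_unscorable} unscorable)"]
        for p in self.phases:
            lines.append(f"\nPhase {p.name} [frames {p.start_frame}-{p.end_frame}]")
            if p.representative is None:
                lines.append("  no scorable frames")
            else:
                r = p.representative
                lines.append(
                    f"  REBA total {r.total} (A={r.score_a}, B={r.score_b}, C={r.score_c}, "
                    f"activity={r.activity}) -> action level {r.action_level}, risk {r.risk.value}"
                )
            for part, grade in p.comfort.items():
                lines.append(f"  comfort {part}: {grade}")
            if p.flagged_high_risk:
                lines.append("  ** flagged: high-risk phase (action level >= 3)")
        if self.flagged_phases:
            lines.append(f"\nHigh-risk phases: {', '.join(self.flagged_phases)}")
        else:
            lines.append("\nNo high-risk phases.")
        return "\n".join(lines)


_COMFORT_ANGLE = {
    # part -> (angle column for the phase peak, prefer operating side max)
    "neck": ("theta1_neck",),
    "trunk": ("theta4_trunk",),
    "knee": ("theta6_thigh_calf_L", "theta6_thigh_calf_R"),
}


def _phase_comfort(series: JointAngleSeries, span: tuple[int, int],
                   thresholds: GradientThresholds) -> dict[str, str]:
    frames = [f for f in series.frames if span[0] <= f.frame_index <= span[1]]
    grades = {}
    for part, cols in _COMFORT_ANGLE.items():
        vals = [getattr(f, c) for f in frames for c in cols]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            continue
        # discomfort peaks at the max deviation (neck/trunk) but at the
        # minimum included angle for the knee (decreasing direction)
        angle = min(vals) if thresholds[part].direction == "decreasing" else max(vals)
        grades[part] = classify_comfort(part, angle, thresholds).value
    return grades


def build_report(
    series: JointAngleSeries,
    config: RebaConfig | None = None,
    annotations: PhaseAnnotation | None = None,
    subject: SubjectInfo | None = None,
    thresholds: GradientThresholds | None = None,
    curve: RiskCurve | None = None,
) -> tuple[AssessmentReport, RiskCurve]:
    """Assemble the full assessment for one angle series.

    Without annotations the whole sequence is treated as a single phase.
    The representative posture per phase is the frame with the maximum REBA
    total inside the phase.
    """
    config = config or RebaConfig()
    thresholds = thresholds or default_thresholds()
    curve = curve or score_sequence(series, config)
    if annotations is None:
        idx = [f.frame_index for f in series.frames]
        annotations = PhaseAnnotation(task="", phases=(("whole_sequence", min(idx), max(idx)),))

    by_index = dict(zip(curve.frame_indices, curve.sheets))
    phases = []
    for name, start, end in annotations.phases:
        peaks = peak_angles(series, (start, end))
        best_sheet, best_frame = None, None
        for i in range(start, end + 1):
            sheet = by_index.get(i)
            if sheet is not None and (best_sheet is None or sheet.total > best_sheet.total):
                best_sheet, best_frame = sheet, i
        flagged = best_sheet is not None and best_sheet.action_level >= HIGH_RISK_ACTION_LEVEL
        phases.append(PhaseResult(
            name=name, start_frame=start, end_frame=end, peak_angles=peaks,
            representative=best_sheet, representative_frame=best_frame,
            comfort=_phase_comfort(series, (start, end), thresholds),
            flagged_high_risk=flagged,
        ))
    n_unscorable = sum(1 for s in curve.sheets if s is None)
    report = AssessmentReport(
        subject=subject or SubjectInfo(), task=annotations.task,
        n_frames=len(series.frames), n_unscorable=n_unscorable, phases=phases,
    )
    return report, curve
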