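"""Simulate a bend-and-reach motion and assess it end to end.

Generates a noisy synthetic floor-pickup sequence (Gaussian keypoint jitter
plus random dropout), cleans it, computes the joint-angle series, scores
every frame with REBA and prints the per-phase assessment report.  The
flagged phase is the bend peak: repeated deep bends are where cumulative
musculoskeletal load concentrates.
"""

from rebakit import (
    BodyModel, NoiseModel, RebaConfig, angles_over_sequence, build_report,
    filter_confidence, generate_sequence, interpolate_gaps, preset_bend_low,
)
from rebakit.report import PhaseAnnotation

body = BodyModel.from_stature(1.64)
traj = preset_bend_low(deep_squat=True)
noise = NoiseModel(gaussian_sd_px=2.0, dropout_prob=0.02, seed=7)
seq, ground_truth = generate_sequence(body, traj, noise)
print(f"simulated {len(seq)} frames of task {traj.task!r} at {traj.fps:g} fps")

seq = interpolate_gaps(filter_confidence(seq, 0.1), max_gap_frames=5)
series = angles_over_sequence(seq, smoothing_window=5)

phases = PhaseAnnotation(traj.task, (
    ("approach", 0, 24), ("bend_peak", 25, 80), ("return", 81, len(seq) - 1)))
report, curve = build_report(series, RebaConfig(muscle_use_a=1), phases)
print(report.to_text())
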