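"""REBA engine: sub-score rules, matrices, sheet assembly, risk mapping."""

import itertools

import numpy as np
import pytest

from rebakit import reba
from rebakit.kinematics import angles_over_sequence, compute_angles
from rebakit.reba import (
    GroupAInputs, GroupBInputs, RebaConfig, RiskLevel, Stance,
    activity_score, assemble_sheet, risk_level, score_A, score_B,
    score_forearm, score_frame, score_legs, score_neck, score_sequence,
    score_trunk, score_upper_arm, score_wrist, table_a, table_b, table_c,
)
from rebakit.skeleton import MotionSequence
from rebakit.synthetic import NoiseModel, PosturePose, forward_kinematics, generate_sequence, preset_bend_low


class TestSubScoreRules:
    @pytest.mark.parametrize("angle,twist,side,expected", [
        (0, False, False, 1),
        (4.9, False, False, 1),     # inside the upright tolerance
        (10, False, False, 2),
        (30, False, False, 3),
        (60, False, False, 3),
        (70, False, False, 4),
        (70, True, False, 5),
        (70, True, True, 5),        # capped
    ])
    def test_trunk(self, angle, twist, side, expected):
        assert score_trunk(angle, twist, side) == expected

    @pytest.mark.parametrize("angle,ext,twist,expected", [
        (10, False, False, 1),
        (20, False, False, 1),
        (25, False, False, 2),
        (10, True, False, 2),       # extension
        (25, False, True, 3),
        (10, False, True, 2),
    ])
    def test_neck(self, angle, ext, twist, expected):
        assert score_neck(angle, ext, twist) == expected

    @pytest.mark.parametrize("stance,knee,expected", [
        (Stance.BILATERAL, 170, 1),
        (Stance.BILATERAL, 135, 2),     # +1 band 120-150
        (Stance.BILATERAL, 150, 2),
        (Stance.BILATERAL, 119, 3),     # +2 below 120
        (Stance.UNILATERAL_OR_UNSTABLE, 170, 2),
        (Stance.UNILATERAL_OR_UNSTABLE, 110, 4),
        (Stance.SITTING, 90, 1),        # knee increment not applied seated
        (Stance.WALKING, 170, 1),
    ])
    def test_legs(self, stance, knee, expected):
        assert score_legs(stance, knee) == expected

    @pytest.mark.parametrize("angle,abd,raised,supported,expected", [
        (10, False, False, False, 1),
        (30, False, False, False, 2),
        (60, False, False, False, 3),
        (95, False, False, False, 4),
        (95, False, False, True, 3),    # external support: -1
        (95, True, True, False, 6),
        (10, False, False, True, 1),    # clamped at 1
    ])
    def test_upper_arm(self, angle, abd, raised, supported, expected):
        assert score_upper_arm(angle, abd, raised, supported) == expected

    @pytest.mark.parametrize("flexion,expected", [
        (80, 1), (60, 1), (100, 1), (30, 2), (110, 2), (0, 2),
    ])
    def test_forearm(self, flexion, expected):
        assert score_forearm(flexion) == expected

    def test_forearm_from_included_angle_convention(self):
        assert score_forearm(180.0 - 100.0) == 1  # elbow included 100 = flexion 80

    @pytest.mark.parametrize("angle,dev,expected", [
        (10, False, 1), (15, False, 1), (30, False, 2),
        (10, True, 2), (30, True, 3),
    ])
    def test_wrist(self, angle, dev, expected):
        assert score_wrist(angle, dev) == expected

    def test_wrist_undefined_uses_default(self):
        assert score_wrist(None) == 1
        assert score_wrist(float("nan"), default=2) == 2

    @pytest.mark.parametrize("kg,shock,expected", [
        (0.1, False, 0), (4.9, False, 0), (5, False, 1), (10, False, 1),
        (12, False, 2), (12, True, 3),
    ])
    def test_load_mapping(self, kg, shock, expected):
        assert reba.load_score_from_kg(kg, shock) == expected


class TestMatrices:
    def test_worked_examples(self):
        assert table_a(3, 1, 2) == 4
        assert table_b(4, 2, 3) == 7

    def test_minima(self):
        assert table_a(1, 1, 1) == 1
        assert table_b(1, 1, 1) == 1
        assert table_c(1, 1) == 1

    def test_sheet_consistency_cells_a(self):
        # consistent with the bend sheet's peak row (A=9 incl. muscle use)
        assert table_a(4, 3, 3) == 8

    def test_sheet_consistency_cells_b(self):
        assert table_b(2, 2, 1) == 2

    @pytest.mark.parametrize("sa,sb,expected", [(3, 9, 7), (5, 2, 4)])
    def test_table_c_cells(self, sa, sb, expected):
        assert table_c(sa, sb) == expected

    def test_table_c_clamps_above_twelve(self):
        assert table_c(13, 14) == table_c(12, 12) == 12

    def test_out_of_range_indices_error(self):
        with pytest.raises(ValueError):
            table_a(0, 1, 1)
        with pytest.raises(ValueError):
            table_a(6, 1, 1)
        with pytest.raises(ValueError):
            table_b(1, 3, 1)
        with pytest.raises(ValueError):
            table_c(0, 1)

    def test_exhaustive_monotonicity(self):
        """Each matrix is non-decreasing in every argument, over all cells."""
        A, B, C = reba.TABLE_A, reba.TABLE_B, reba.TABLE_C
        for M in (A, B, C):
            for axis in range(M.ndim):
                assert (np.diff(M, axis=axis) >= 0).all()

    def test_bounds(self):
        assert reba.TABLE_A.min() == 1 and reba.TABLE_A.max() == 9
        assert reba.TABLE_B.min() == 1 and reba.TABLE_B.max() == 9
        assert reba.TABLE_C.min() == 1 and reba.TABLE_C.max() == 12


class TestGroupScores:
    def test_score_a_additive(self):
        assert score_A(GroupAInputs(2, 2, 1, load_score=1, muscle_use=1)) == 5
        assert score_A(GroupAInputs(1, 1, 1)) == 1

    def test_score_b_additive(self):
        assert score_B(GroupBInputs(1, 1, 1, coupling_load_score=1, muscle_use=0)) == 2

    def test_input_validation(self):
        with pytest.raises(ValueError):
            GroupAInputs(0, 1, 1)
        with pytest.raises(ValueError):
            GroupBInputs(1, 1, 4)
        with pytest.raises(ValueError):
            GroupAInputs(1, 1, 1, muscle_use=2)


class TestActivityAndRisk:
    def test_activity_sums_flags(self):
        assert activity_score() == 0
        assert activity_score(True, True, True) == 3
        assert activity_score(static_over_1min=True) == 1

    @pytest.mark.parametrize("total,level,label", [
        (1, 0, RiskLevel.NEGLIGIBLE),
        (2, 1, RiskLevel.LOW), (3, 1, RiskLevel.LOW),
        (4, 2, RiskLevel.MEDIUM), (5, 2, RiskLevel.MEDIUM), (7, 2, RiskLevel.MEDIUM),
        (8, 3, RiskLevel.HIGH), (10, 3, RiskLevel.HIGH),
        (11, 4, RiskLevel.VERY_HIGH), (12, 4, RiskLevel.VERY_HIGH),
        (15, 4, RiskLevel.VERY_HIGH),
    ])
    def test_mapping(self, total, level, label):
        assert risk_level(total) == (level, label)

    def test_partition_has_no_gaps_or_overlaps(self):
        levels = [risk_level(t) for t in range(1, 16)]
        assert len(levels) == 15  # total over [1,15] always maps
        assert [l for l, _ in levels] == sorted(l for l, _ in levels)

    @pytest.mark.parametrize("total", [0, 16, -1])
    def test_out_of_range(self, total):
        with pytest.raises(ValueError):
            risk_level(total)


# printed score-sheet rows: (trunk, neck, legs, load, muscle) -> A,
# (upper arm, forearm, wrist, load, muscle) -> B, total, action level
BEND_SHEET = {
    "a": ((1, 1, 1, 0, 0), 1, (1, 1, 1, 0, 0), 1, 1, 0),
    "b": ((1, 2, 1, 0, 0), 1, (1, 1, 1, 0, 0), 1, 1, 0),
    "c": ((2, 2, 1, 0, 1), 4, (1, 2, 1, 0, 0), 1, 3, 1),
    "d": ((3, 2, 2, 0, 1), 6, (1, 2, 1, 0, 0), 1, 6, 2),
    "e": ((4, 3, 3, 0, 1), 9, (2, 2, 1, 0, 0), 2, 9, 3),
    "g": ((4, 3, 2, 1, 1), 9, (2, 1, 2, 1, 1), 4, 10, 3),
    "h": ((2, 2, 1, 1, 1), 5, (1, 1, 1, 1, 0), 2, 4, 2),
    "i": ((1, 1, 1, 0, 0), 1, (1, 1, 1, 0, 0), 1, 1, 0),
}
REACH_SHEET = {
    "b": ((1, 1, 1, 1, 1), 3, (4, 1, 2, 1, 1), 7, 6, 2),
    "c": ((1, 1, 1, 1, 0), 2, (3, 2, 2, 1, 1), 7, 5, 2),
    "d": ((1, 1, 1, 1, 0), 2, (2, 2, 2, 1, 0), 4, 3, 1),
    "e": ((2, 2, 2, 1, 1), 6, (2, 2, 2, 1, 0), 4, 7, 2),
}


class TestScoreSheetReproduction:
    @pytest.mark.parametrize("row", sorted(BEND_SHEET))
    def test_bend_rows(self, row):
        ga, exp_a, gb, exp_b, exp_total, exp_level = BEND_SHEET[row]
        sheet = assemble_sheet(GroupAInputs(*ga), GroupBInputs(*gb), activity=0)
        assert (sheet.score_a, sheet.score_b, sheet.total) == (exp_a, exp_b, exp_total)
        assert sheet.action_level == exp_level

    @pytest.mark.parametrize("row", sorted(REACH_SHEET))
    def test_reach_rows(self, row):
        ga, exp_a, gb, exp_b, exp_total, exp_level = REACH_SHEET[row]
        sheet = assemble_sheet(GroupAInputs(*ga), GroupBInputs(*gb), activity=0)
        assert (sheet.score_a, sheet.score_b, sheet.total) == (exp_a, exp_b, exp_total)
        assert sheet.action_level == exp_level

    def test_deepest_bend_row_risk_follows_score_band(self):
        # the worksheet's deepest-bend row: its total 11 maps to very_high
        sheet = assemble_sheet(GroupAInputs(4, 3, 3, 1, 1), GroupBInputs(2, 1, 2, 1, 1))
        assert (sheet.score_a, sheet.score_b, sheet.total) == (10, 4, 11)
        assert sheet.risk is RiskLevel.VERY_HIGH


class TestAssembly:
    def test_all_minima(self):
        sheet = assemble_sheet(GroupAInputs(1, 1, 1), GroupBInputs(1, 1, 1))
        assert sheet.total == 1 and sheet.risk is RiskLevel.NEGLIGIBLE

    def test_maximum_over_full_input_space_is_15(self):
        best = 0
        for trunk, neck, legs in itertools.product(range(1, 6), range(1, 4), range(1, 5)):
            for ua, fa, wr in itertools.product(range(1, 7), range(1, 3), range(1, 4)):
                a = reba.table_a(trunk, neck, legs) + 3 + 1
                b = reba.table_b(ua, fa, wr) + 3 + 1
                best = max(best, min(reba.table_c(a, b) + 3, 15))
        assert best == 15

    def test_totals_never_exceed_15(self):
        sheet = assemble_sheet(GroupAInputs(5, 3, 4, 3, 1), GroupBInputs(6, 3, 3, 3, 1),
                               activity=3)
        assert sheet.total == 15 and sheet.risk is RiskLevel.VERY_HIGH


class TestScoreFromAngles:
    def test_upright_pose_scores_one(self, body):
        angles = compute_angles(forward_kinematics(body, PosturePose()))
        sheet = score_frame(angles, RebaConfig())
        assert sheet.total == 1 and sheet.risk is RiskLevel.NEGLIGIBLE

    def test_deep_bend_with_muscle_use_is_high_risk(self, body):
        # trunk 70 -> 4, neck 25 -> 2, knee 110 -> legs 3; A = 7+1 = 8
        pose = PosturePose(trunk=70, neck=25, shoulder_l=10, shoulder_r=10,
                           elbow_l=170, elbow_r=170, hip_l=70, hip_r=70,
                           knee_l=110, knee_r=110)
        angles = compute_angles(forward_kinematics(body, pose))
        sheet = score_frame(angles, RebaConfig(muscle_use_a=1))
        assert sheet.total >= 8
        assert sheet.action_level >= 3

    def test_side_policy_max_takes_worse_side(self, body):
        pose = PosturePose(shoulder_l=10, shoulder_r=120, elbow_l=100, elbow_r=100)
        angles = compute_angles(forward_kinematics(body, pose))
        mx = score_frame(angles, RebaConfig(side_policy="max"))
        left = score_frame(angles, RebaConfig(side_policy="left"))
        right = score_frame(angles, RebaConfig(side_policy="right"))
        assert right.total > left.total
        assert mx.total == right.total and mx.side == "R"

    def test_unscorable_frame_returns_none(self, body):
        frame = forward_kinematics(body, PosturePose())
        kps = {k: v for k, v in frame.keypoints.items() if k != "Neck"}
        angles = compute_angles(frame.__class__(0, 0.0, kps))
        assert score_frame(angles) is None

    def test_constant_sequence_gives_constant_curve(self, body):
        frames = [forward_kinematics(body, PosturePose(trunk=30), frame_index=i)
                  for i in range(6)]
        series = angles_over_sequence(MotionSequence(frames), smoothing_window=1)
        curve = score_sequence(series)
        assert len(set(curve.totals)) == 1

    def test_unscorable_frames_flagged_not_dropped(self, body):
        seq, _ = generate_sequence(body, preset_bend_low(),
                                   NoiseModel(seed=9, dropout_prob=0.6))
        series = angles_over_sequence(seq, smoothing_window=1)
        curve = score_sequence(series)
        assert len(curve) == len(seq)
        assert any(s is None for s in curve.sheets)


class TestConfig:
    def test_yaml_like_dict_round_trip(self):
        cfg = RebaConfig.from_dict({"load_kg": 6.0, "stance": "sitting",
                                    "side_policy": "right"})
        assert cfg.effective_load_score() == 1
        assert cfg.stance is Stance.SITTING

    def test_explicit_load_score_overrides_kg(self):
        assert RebaConfig(load_kg=20.0, load_score=0).effective_load_score() == 0

    def test_bad_side_policy(self):
        with pytest.raises(ValueError):
            RebaConfig(side_policy="both")
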