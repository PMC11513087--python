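"""Grade joint angles on the comfort gradient and refit it from samples.

The shipped gradient encodes, per body part, the boundary angles between
what elderly subjects call easy, moderate and strenuous.  This script grades
a few angles against it, then simulates a labelled cohort (42 subjects per
boundary level), refits the boundaries from the samples, and runs the
one-way ANOVA + Tukey-HSD check that the four levels are distinguishable.
"""

import numpy as np

from rebakit import classify_comfort, default_thresholds, fit_thresholds, one_way_anova, tukey_hsd
from rebakit.comfort import BOUNDARY_LABELS

thresholds = default_thresholds()
for part, angle in [("neck", 30), ("neck", 58), ("trunk", 35), ("knee", 160), ("knee", 130)]:
    grade = classify_comfort(part, angle, thresholds)
    print(f"{part:6s} {angle:5.1f} deg -> {grade.value}")

# synthetic labelled cohort: Normal draws around each published boundary mean
rng = np.random.default_rng(42)
n = 42
rows, neck_groups = [], []
for part in ("neck", "trunk", "knee"):
    for label, mean in zip(BOUNDARY_LABELS, thresholds[part].boundaries()):
        draws = rng.normal(mean, thresholds[part].sd[label], size=n)
        rows += [(part, label, float(v)) for v in draws]
        if part == "neck":
            neck_groups.append(draws)

fitted = fit_thresholds(rows)
print("\nrefitted boundaries (deg):")
for part in ("neck", "trunk", "knee"):
    bounds = ", ".join(f"{b:.1f}" for b in fitted[part].boundaries())
    print(f"  {part:6s} [{fitted[part].direction}]: {bounds}")

res = one_way_anova(neck_groups)
print(f"\nneck ANOVA: SS_between={res.sum_sq_between:.1f} df={res.df_between} "
      f"MS={res.mean_sq_between:.1f} F={res.f_stat:.1f} p={res.p_value:.2e}")
worst = max(tukey_hsd(neck_groups), key=lambda p: p.p_value)
print(f"largest Tukey-HSD p across neck level pairs: {worst.p_value:.3g} "
      f"(levels {BOUNDARY_LABELS[worst.group_i]} vs {BOUNDARY_LABELS[worst.group_j]})")
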