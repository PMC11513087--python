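"""Comfort-gradient model for neck, trunk and knee angles.

Elderly subjects performing bend-and-reach tasks can reliably distinguish
"easy", "moderate" and "strenuous" joint configurations.  The gradient model
encodes that as four boundary angles per body part — the normal (resting)
angle, the easy-to-moderate boundary, the moderate-to-laborious boundary and
the most-laborious point.  For the neck and trunk discomfort grows with the
deviation angle (increasing direction); for the knee it grows as the included
angle closes from straight (decreasing direction).

The shipped default boundaries are the study means:

    neck   17° / 49° / 57° / 60°      (increasing)
    trunk   1° / 12° / 28° / 40°      (increasing)
    knee  179° / 151° / 139° / 126°   (decreasing)

``fit_thresholds`` re-estimates boundaries from labelled angle samples, and
``one_way_anova`` / ``tukey_hsd`` provide the distinguishability check that
the four labelled levels differ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComfortGrade",
    "PartThresholds",
    "GradientThresholds",
    "AnovaResult",
    "TukeyPair",
    "default_thresholds",
    "classify_comfort",
    "fit_thresholds",
    "one_way_anova",
    "tukey_hsd",
]

BOUNDARY_LABELS = ("normal", "easy_to_moderate", "moderate_to_laborious", "most_laborious")


class ComfortGrade(str, Enum):
    NORMAL = "normal"
    EASY = "easy"
    MODERATE = "moderate"
    STRENUOUS = "strenuous"
    BEYOND_STRENUOUS = "beyond_strenuous"


@dataclass(frozen=True)
class PartThresholds:
    """Boundary angles for one body part, in degrees."""

    part: str
    normal: float
    easy_to_moderate: float
    moderate_to_laborious: float
    most_laborious: float
    direction: str  # "increasing" (discomfort grows with angle) or "decreasing"
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = (self.normal, self.easy_to_moderate, self.moderate_to_laborious,
             self.most_laborious)
        if self.direction == "increasing":
            ok = b[0] < b[1] < b[2] < b[3]
        elif self.direction == "decreasing":
            ok = b[0] > b[1] > b[2] > b[3]
        else:
            raise ValueError(f"direction must be 'increasing' or 'decreasing', got {self.direction!r}")
        if not ok:
            raise ValueError(
                f"{self.part}: boundaries {b} are not monotone {self.direction}"
            )

    def boundaries(self) -> tuple[float, float, float, float]:
        return (self.normal, self.easy_to_moderate, self.moderate_to_laborious,
                self.most_laborious)


@dataclass(frozen=True)
class GradientThresholds:
    """Per-part comfort boundaries (neck, trunk, knee by default)."""

    parts: dict[str, PartThresholds]

    def __getitem__(self, part: str) -> PartThresholds:
        try:
            return self.parts[part]
        except KeyError:
            raise KeyError(
                f"unknown body part {part!r}; known parts: {sorted(self.parts)}"
            ) from None

    def to_json(self, path) -> None:
        doc = {
            p: {"boundaries": dict(zip(BOUNDARY_LABELS, t.boundaries())),
                "direction": t.direction, "sd": t.sd}
            for p, t in self.parts.items()
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GradientThresholds":
        with open(path) as fh:
            doc = json.load(fh)
        parts = {
            p: PartThresholds(p, *(d["boundaries"][k] for k in BOUNDARY_LABELS),
                              direction=d["direction"], sd=d.get("sd", {}))
            for p, d in doc.items()
        }
        return cls(parts)


def default_thresholds() -> GradientThresholds:
    """The shipped comfort boundaries (study cohort means, degrees)."""
    return GradientThresholds({
        "neck": PartThresholds("neck", 17.0, 49.0, 57.0, 60.0, "increasing",
                               sd={"normal": 2.41, "easy_to_moderate": 3.00,
                                   "moderate_to_laborious": 4.83, "most_laborious": 4.79}),
        "trunk": PartThresholds("trunk", 1.0, 12.0, 28.0, 40.0, "increasing",
                                sd={"normal": 0.64, "easy_to_moderate": 1.42,
                                    "moderate_to_laborious": 2.44, "most_laborious": 3.31}),
        "knee": PartThresholds("knee", 179.0, 151.0, 139.0, 126.0, "decreasing",
                               sd={"normal": 0.69, "easy_to_moderate": 1.73,
                                   "moderate_to_laborious": 2.45, "most_laborious": 3.56}),
    })


def classify_comfort(part: str, angle: float,
                     thresholds: GradientThresholds | None = None) -> ComfortGrade:
    """Grade one angle against a part's comfort boundaries.

    Increasing parts: [normal, e2m) → easy, [e2m, m2l) → moderate,
    [m2l, most] → strenuous; below normal → normal, above the most-laborious
    point → beyond_strenuous.  Decreasing parts (knee) mirror the
    inequalities.  Out-of-band angles are graded, never clamped.
    """
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"angle must be in [0, 180] degrees, got {angle!r}")
    t = (thresholds or default_thresholds())[part]
    n, e2m, m2l, most = t.boundaries()
    if t.direction == "increasing":
        if angle < n:
            return ComfortGrade.NORMAL
        if angle < e2m:
            return ComfortGrade.EASY
        if angle < m2l:
            return ComfortGrade.MODERATE
        if angle <= most:
            return ComfortGrade.STRENUOUS
        return ComfortGrade.BEYOND_STRENUOUS
    if angle > n:
        return ComfortGrade.NORMAL
    if angle > e2m:
        return ComfortGrade.EASY
    if angle > m2l:
        return ComfortGrade.MODERATE
    if angle >= most:
        return ComfortGrade.STRENUOUS
    return ComfortGrade.BEYOND_STRENUOUS


def fit_thresholds(samples) -> GradientThresholds:
    """Estimate comfort boundaries from labelled samples.

    ``samples`` is an iterable of (part, label, angle) with labels from
    ``BOUNDARY_LABELS`` (or a DataFrame with part/label/angle columns).  Each
    boundary is the cell mean; the cell SD is reported alongside; the
    direction is inferred from the monotone ordering of the means.  Every
    (part, label) cell needs at least two samples, and non-monotone means
    raise an error naming the part.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples[["part", "label", "angle"]].copy()
    else:
        df = pd.DataFrame(list(samples), columns=["part", "label", "angle"])
    bad = sorted(set(df["label"]) - set(BOUNDARY_LABELS))
    if bad:
        raise ValueError(f"unknown labels {bad}; expected {BOUNDARY_LABELS}")
    parts = {}
    for part, g in df.groupby("part"):
        means, sds = {}, {}
        for label in BOUNDARY_LABELS:
            cell = g.loc[g["label"] == label, "angle"].to_numpy(dtype=float)
            if len(cell) < 2:
                raise ValueError(
                    f"{part}/{label}: need at least 2 samples per cell, got {len(cell)}"
                )
            means[label] = float(cell.mean())
            sds[label] = float(cell.std(ddof=1))
        ordered = [means[l] for l in BOUNDARY_LABELS]
        if all(a < b for a, b in zip(ordered, ordered[1:])):
            direction = "increasing"
        elif all(a > b for a, b in zip(ordered, ordered[1:])):
            direction = "decreasing"
        else:
            raise ValueError(f"{part}: cell means {ordered} are not monotone")
        parts[part] = PartThresholds(part, *ordered, direction=direction, sd=sds)
    return GradientThresholds(parts)


@dataclass(frozen=True)
class AnovaResult:
    """One-way (between-groups) ANOVA decomposition."""

    sum_sq_between: float
    df_between: int
    # within-group fields are optional so a between-only table row (printed
    # SS and df) can still be represented and its mean square derived
    sum_sq_within: float = 0.0
    df_within: int = 0
    f_stat: float = math.nan
    p_value: float = math.nan
    group_means: tuple[float, ...] = ()
    group_sds: tuple[float, ...] = ()

    @property
    def mean_sq_between(self) -> float:
        return self.sum_sq_between / self.df_between

    @property
    def mean_sq_within(self) -> float:
        return self.sum_sq_within / self.df_within

    @property
    def sum_sq_total(self) -> float:
        return self.sum_sq_between + self.sum_sq_within

    def to_row(self, name: str = "") -> dict:
        return {"variable": name, "sum_sq": self.sum_sq_between, "df": self.df_between,
                "mean_sq": self.mean_sq_between, "F": self.f_stat, "p": self.p_value}


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition.

    ``groups`` is a list of sample arrays, one per level.  SS_between is the
    size-weighted squared deviation of group means from the grand mean;
    SS_within pools squared deviations inside groups; F = MS_between /
    MS_within with a p-value from the F(df_between, df_within) distribution.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need at least 2 groups with at least 2 samples each")
    ns = np.array([len(a) for a in arrs])
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_between = len(arrs) - 1
    df_within = int(ns.sum()) - len(arrs)
    if ss_within == 0.0:
        # all groups internally constant: F undefined when means also equal
        f = math.nan if ss_between == 0.0 else math.inf
        p = math.nan if ss_between == 0.0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(ss_between, df_between, ss_within, df_within, f, p,
                       group_means=tuple(float(m) for m in means),
                       group_sds=tuple(float(a.std(ddof=1)) for a in arrs))


@dataclass(frozen=True)
class TukeyPair:
    group_i: int
    group_j: int
    mean_diff: float
    p_value: float
    ci_low: float
    ci_high: float


def tukey_hsd(groups, confidence: float = 0.95) -> list[TukeyPair]:
    """All-pairs Tukey-HSD comparison using the studentized range.

    Delegates to the studentized-range implementation in scipy, which uses
    the Tukey-Kramer form for unequal group sizes.  Returns one record per
    unordered pair (i < j) with the mean difference (i - j), p-value and
    confidence interval.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need at least 2 groups with at least 2 samples each")
    res = stats.tukey_hsd(*arrs)
    ci = res.confidence_interval(confidence_level=confidence)
    out = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            out.append(TukeyPair(i, j,
                                 float(res.statistic[i, j]),
                                 float(res.pvalue[i, j]),
                                 float(ci.low[i, j]),
                                 float(ci.high[i, j])))
    return out
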