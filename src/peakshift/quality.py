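"""Post-harvest fruit quality metrics and the treatment-comparison battery.

Derived metrics: dry-matter ratio, weight-band commercial grade (3L..S plus
nonstandard), and premium / marketable class ratios.  Statistics: continuous
traits are gated per group by Shapiro-Wilk normality (alpha 0.05) into either
one-way ANOVA with Tukey's HSD or the Mann-Whitney U test; grade tables get a
Pearson chi-square plus per-grade pooled two-proportion z-tests with
Bonferroni correction; class ratios get plain two-proportion z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "GRADE_ORDER",
    "GRADE_THRESHOLDS_G",
    "QualityRecord",
    "GradeTable",
    "ContinuousTestReport",
    "ProportionTestReport",
    "GradeTestReport",
    "dm_ratio",
    "assign_grade",
    "class_ratios",
    "compare_continuous",
    "grade_distribution_tests",
    "two_proportion_z",
]

# Strict lower bounds in grams: a fruit weighing exactly the boundary falls
# to the lower grade (3L requires > 23 g, ...; <= 6 g is nonstandard).
GRADE_ORDER = ("3L", "2L", "L", "M", "S")
GRADE_THRESHOLDS_G = {"3L": 23.0, "2L": 18.0, "L": 14.0, "M": 10.0, "S": 6.0}

CLASS_LABELS = ("KJ", "B", "N")  # premium, standard, non-standard appearance


@dataclass(frozen=True)
class QualityRecord:
    """Per-fruit morphological and biochemical measurements plus class label."""

    fruit_id: str
    fresh_weight: float  # g
    diam_max: float  # mm
    diam_min: float  # mm
    length: float  # mm
    ssc: float  # Brix%
    class_label: str
    dry_weight: Optional[float] = None  # g

    def __post_init__(self) -> None:
        if self.fresh_weight <= 0:
            raise ValueError(f"fresh_weight must be positive, got {self.fresh_weight}")
        if self.dry_weight is not None and not 0 <= self.dry_weight < self.fresh_weight:
            raise ValueError("dry_weight must lie in [0, fresh_weight)")
        if self.diam_min > self.diam_max:
            raise ValueError("diam_min exceeds diam_max")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")

    @property
    def grade(self) -> str:
        return assign_grade(self.fresh_weight)


@dataclass(frozen=True)
class GradeTable:
    """Counts over the graded weight bands for two (or more) groups.

    Nonstandard (<= 6 g) fruits are excluded from the tested bands.
    """

    counts: Mapping[str, Mapping[str, int]]  # group -> grade -> count

    def __post_init__(self) -> None:
        for group, row in self.counts.items():
            for grade, c in row.items():
                if grade not in GRADE_ORDER:
                    raise ValueError(f"unknown grade {grade!r} in group {group!r}")
                if c < 0:
                    raise ValueError("counts must be nonnegative")

    def group_total(self, group: str) -> int:
        return sum(self.counts[group].values())

    def as_matrix(self, grades: Sequence[str] = GRADE_ORDER) -> np.ndarray:
        return np.array(
            [[self.counts[g].get(grade, 0) for grade in grades] for g in self.counts]
        )


def dm_ratio(dry_g: float, fresh_g: float) -> float:
    """Dry-matter ratio in percent: 100 * dry / fresh."""
    if fresh_g <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_g}")
    if not 0 <= dry_g < fresh_g:
        raise ValueError(f"dry weight {dry_g} must lie in [0, fresh weight {fresh_g})")
    return 100.0 * dry_g / fresh_g


def assign_grade(fresh_weight_g: float) -> str:
    """Commercial weight grade; boundary weights fall to the lower grade."""
    if fresh_weight_g <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_weight_g}")
    for grade in GRADE_ORDER:
        if fresh_weight_g > GRADE_THRESHOLDS_G[grade]:
            return grade
    return "nonstandard"


def class_ratios(records: Iterable[QualityRecord]) -> tuple[float, float]:
    """(premium %, marketable %) of a harvest lot.

    Premium = share of KJ fruits; marketable = share of KJ + B fruits.
    """
    labels = [r.class_label for r in records]
    if not labels:
        raise ValueError("no records")
    n = len(labels)
    n_kj = labels.count("KJ")
    n_b = labels.count("B")
    return 100.0 * n_kj / n, 100.0 * (n_kj + n_b) / n


@dataclass(frozen=True)
class ContinuousTestReport:
    metric: str
    test: str  # "ANOVA+Tukey HSD" or "Mann-Whitney U"
    statistic: float
    pvalue: float
    normal_groups: tuple[bool, ...]
    tukey_reject: Optional[bool] = None


def compare_continuous(
    group_a: Sequence[float],
    group_b: Sequence[float],
    metric: str = "",
    alpha: float = 0.05,
) -> ContinuousTestReport:
    """Normality-gated two-group location comparison.

    Shapiro-Wilk on each group at ``alpha``; if both pass, one-way ANOVA with
    a Tukey HSD pairwise decision (coincident with the F-test for two
    groups); otherwise Mann-Whitney U (two-sided).  Constant-valued groups
    have undefined normality and fall to Mann-Whitney with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")

    def _normal(x: np.ndarray) -> Optional[bool]:
        if np.ptp(x) == 0:
            return None
        return stats.shapiro(x).pvalue > alpha

    na, nb = _normal(a), _normal(b)
    if na is None or nb is None:
        warnings.warn(
            f"{metric or 'metric'}: constant-valued group, normality undefined; "
            "using Mann-Whitney U",
            stacklevel=2,
        )
    if na and nb:
        res = stats.f_oneway(a, b)
        tukey = pairwise_tukeyhsd(
            np.concatenate([a, b]), ["A"] * a.size + ["B"] * b.size, alpha=alpha
        )
        return ContinuousTestReport(
            metric, "ANOVA+Tukey HSD", float(res.statistic), float(res.pvalue),
            (True, True), bool(tukey.reject[0]),
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ContinuousTestReport(
        metric, "Mann-Whitney U", float(res.statistic), float(res.pvalue),
        (bool(na), bool(nb)),
    )


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z-test (two-sided).

    z = (p1 - p2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2)).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError(f"invalid count/size pair ({x}, {n})")
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1): z undefined")
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p)


@dataclass(frozen=True)
class ProportionTestReport:
    label: str
    z: float
    p_raw: float
    p_adj: Optional[float] = None


@dataclass(frozen=True)
class GradeTestReport:
    chi2: float
    df: int
    pvalue: float
    per_grade: tuple[ProportionTestReport, ...]


def grade_distribution_tests(table: GradeTable) -> GradeTestReport:
    """Pearson chi-square over a two-group grade table, plus per-grade pooled
    two-proportion z-tests Bonferroni-corrected over the tested grades.

    Grades with a zero total across both groups are excluded with a warning
    (their expected counts would be zero).
    """
    groups = list(table.counts)
    if len(groups) != 2:
        raise ValueError("grade tests compare exactly two groups")
    grades = [g for g in GRADE_ORDER if any(table.counts[gr].get(g, 0) for gr in groups)]
    dropped = [g for g in GRADE_ORDER if g not in grades]
    if dropped:
        warnings.warn(f"grades with zero margin excluded from tests: {dropped}", stacklevel=2)
    if len(grades) < 2:
        raise ValueError("need at least two grades with nonzero margins")
    obs = table.as_matrix(grades)
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    n1, n2 = table.group_total(groups[0]), table.group_total(groups[1])
    m = len(grades)
    per_grade = []
    for grade in grades:
        x1 = table.counts[groups[0]].get(grade, 0)
        x2 = table.counts[groups[1]].get(grade, 0)
        z, p_raw = two_proportion_z(x1, n1, x2, n2)
        per_grade.append(ProportionTestReport(grade, z, p_raw, min(1.0, m * p_raw)))
    return GradeTestReport(float(chi2), int(df), float(p), tuple(per_grade))
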