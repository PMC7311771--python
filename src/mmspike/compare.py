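"""Pairwise group comparisons: Kruskal–Wallis and Kolmogorov–Smirnov matrices,
t-tests on head excursions, and Cohen's d / Glass's Delta effect sizes.

P-value matrices are reported raw, without multiple-comparison correction,
and annotated with one star for p < 0.05 and two for p < 0.01.  Effect sizes
use the equal-weight pooled SD for Cohen's d,

    d = (M2 - M1) / sqrt((SD1^2 + SD2^2) / 2),

and the control group's SD for Glass's Delta (the typically developing group
is the control in diagnosis contrasts).  Magnitudes are labelled on the
conventional ladder: 0.01 very small, 0.2 small, 0.5 medium, 0.8 large,
1.2 very large, 2.0 huge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mmspike.errors import ValidationError

__all__ = [
    "ComparisonMatrix",
    "EffectSizeReport",
    "star",
    "kruskal_wallis_matrix",
    "ks_matrix",
    "pairwise_matrix",
    "excursion_ttest",
    "cohen_d",
    "glass_delta",
    "effect_magnitude",
    "effect_size_report",
]

MAGNITUDE_LADDER = (
    (2.0, "huge"),
    (1.2, "very large"),
    (0.8, "large"),
    (0.5, "medium"),
    (0.2, "small"),
    (0.01, "very small"),
)


def star(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """Significance annotation: '**' below alpha2, '*' below alpha1, else ''."""
    if p < alpha2:
        return "**"
    if p < alpha1:
        return "*"
    return ""


@dataclass(frozen=True)
class ComparisonMatrix:
    """Pairwise p-value or effect-size matrix with significance annotation.

    ``values`` and ``annotation`` are DataFrames sharing row/column labels.
    Within-group matrices are symmetric with a unit p-value diagonal; cross
    matrices (rows one diagnosis, columns the other) need not be.
    """

    statistic_name: str
    values: pd.DataFrame
    annotation: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def render_text(self) -> str:
        """Star-annotated plain-text rendering of the matrix."""
        out = [self.statistic_name]
        cells = self.values.copy().astype(object)
        for i in cells.index:
            for j in cells.columns:
                cells.loc[i, j] = f"{self.values.loc[i, j]:.3g}{self.annotation.loc[i, j]}"
        out.append(cells.to_string())
        return "\n".join(out) + "\n"


def _two_sample_p(test: str, x: np.ndarray, y: np.ndarray) -> float:
    if test == "kruskal":
        if np.array_equal(np.sort(x), np.sort(y)):
            return 1.0  # identical samples: H = 0 (guards the all-ties case)
        return float(stats.kruskal(x, y).pvalue)
    if test == "ks":
        return float(stats.ks_2samp(x, y).pvalue)
    raise ValidationError(f"unknown test {test!r}")


def pairwise_matrix(
    groups: Mapping[str, Sequence[float]],
    test: str,
    statistic_name: str | None = None,
    columns: Mapping[str, Sequence[float]] | None = None,
    alpha1: float = 0.05,
    alpha2: float = 0.01,
) -> ComparisonMatrix:
    """Build a pairwise p-value matrix over groups.

    With only ``groups`` the matrix is square and symmetric with unit
    diagonal.  With ``columns`` given, rows come from ``groups`` and columns
    from ``columns`` (the between-diagnosis layout).
    """
    rows = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    cols = rows if columns is None else {
        k: np.asarray(v, dtype=float) for k, v in columns.items()
    }
    if len(rows) < 1 or len(cols) < 2 - (columns is not None):
        raise ValidationError("need at least 2 groups to compare")
    for name, v in {**rows, **cols}.items():
        if v.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    vals = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    for i, xi in rows.items():
        for j, yj in cols.items():
            if columns is None and i == j:
                vals.loc[i, j] = 1.0
            elif columns is None and not np.isnan(vals.loc[j, i]):
                vals.loc[i, j] = vals.loc[j, i]  # symmetry by construction
            else:
                vals.loc[i, j] = _two_sample_p(test, xi, yj)
    ann = vals.map(lambda p: star(p, alpha1, alpha2))
    name = statistic_name or {"kruskal": "Kruskal-Wallis p", "ks": "Kolmogorov-Smirnov p"}[test]
    return ComparisonMatrix(statistic_name=name, values=vals, annotation=ann)


def kruskal_wallis_matrix(
    groups: Mapping[str, Sequence[float]],
    columns: Mapping[str, Sequence[float]] | None = None,
    statistic_name: str = "Kruskal-Wallis p",
    alpha1: float = 0.05,
    alpha2: float = 0.01,
) -> ComparisonMatrix:
    """Pairwise Kruskal–Wallis (nonparametric ANOVA) p-value matrix."""
    return pairwise_matrix(groups, "kruskal", statistic_name, columns, alpha1, alpha2)


def ks_matrix(
    groups: Mapping[str, Sequence[float]],
    columns: Mapping[str, Sequence[float]] | None = None,
    statistic_name: str = "Kolmogorov-Smirnov p",
    alpha1: float = 0.05,
    alpha2: float = 0.01,
) -> ComparisonMatrix:
    """Pairwise two-sample Kolmogorov–Smirnov p-value matrix."""
    return pairwise_matrix(groups, "ks", statistic_name, columns, alpha1, alpha2)


def excursion_ttest(
    group_a: Sequence[float], group_b: Sequence[float], variant: str = "welch"
) -> float:
    """Two-sample t-test p-value on cumulative excursions.

    Welch (unequal variances) by default — group variances differ markedly in
    practice — with the pooled-variance Student's t available via
    ``variant="student"``.  Identical groups give t = 0, p = 1.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if np.std(x) == 0 and np.std(y) == 0:
        if x.mean() == y.mean():
            return 1.0
        raise ValidationError("zero variance in both groups with unequal means")
    if variant == "welch":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif variant == "student":
        res = stats.ttest_ind(x, y, equal_var=True)
    else:
        raise ValidationError(f"unknown t-test variant {variant!r}")
    return float(res.pvalue)


def cohen_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with the equal-weight pooled SD sqrt((SD1^2 + SD2^2)/2).

    Sign convention: positive when group_b's mean exceeds group_a's.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 values")
    sd1, sd2 = np.std(x, ddof=1), np.std(y, ddof=1)
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        raise ValidationError("both group SDs are zero; d undefined")
    return float((y.mean() - x.mean()) / pooled)


def glass_delta(group_treatment: Sequence[float], group_control: Sequence[float]) -> float:
    """Glass's Delta: mean difference scaled by the control group's SD only."""
    x = np.asarray(group_treatment, dtype=float)
    y = np.asarray(group_control, dtype=float)
    if x.size < 1 or y.size < 2:
        raise ValidationError("treatment needs >= 1 value, control >= 2")
    sd_control = np.std(y, ddof=1)
    if sd_control == 0:
        raise ValidationError("control SD is zero; Delta undefined")
    return float((x.mean() - y.mean()) / sd_control)


def effect_magnitude(value: float) -> str:
    """Label |value| on the very small .. huge ladder."""
    mag = abs(value)
    for threshold, label in MAGNITUDE_LADDER:
        if mag >= threshold:
            return label
    return "very small"


@dataclass(frozen=True)
class EffectSizeReport:
    """Effect sizes for one cell and parameter (signed; labels use |value|)."""

    cell: str
    parameter: str
    cohen_d: float
    glass_delta: float
    p_value: float

    @property
    def cohen_label(self) -> str:
        return effect_magnitude(self.cohen_d)

    @property
    def glass_label(self) -> str:
        return effect_magnitude(self.glass_delta)


def effect_size_report(
    cell: str,
    parameter: str,
    treatment: Sequence[float],
    control: Sequence[float],
    ttest_variant: str = "welch",
) -> EffectSizeReport:
    """Cohen's d, Glass's Delta (control SD) and t-test p for one contrast."""
    return EffectSizeReport(
        cell=cell,
        parameter=parameter,
        cohen_d=cohen_d(control, treatment),
        glass_delta=glass_delta(treatment, control),
        p_value=excursion_ttest(treatment, control, variant=ttest_variant),
    )
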