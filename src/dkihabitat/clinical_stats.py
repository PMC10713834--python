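"""Group comparisons for the participant-characteristics table.

Categorical imaging signs are compared between IDH classes with the Pearson
chi-square test (no continuity correction); quantitative variables with the
pooled-variance two-sample t test when both classes pass a Shapiro-Wilk
normality gate, otherwise the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError
from .synthetic_cohort import CLINICAL_COLUMNS, ClinicalRecord, cohort_to_frame

__all__ = [
    "ContingencyTable",
    "GroupComparison",
    "chi_square_test",
    "students_t_test",
    "mann_whitney_u",
    "crosstab",
    "build_table1",
    "format_p",
]


@dataclass
class ContingencyTable:
    """An r x c table of non-negative counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) == 0).any() or (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every margin must be positive")


@dataclass
class GroupComparison:
    """One between-group test: the statistic, degrees of freedom, p-value."""

    variable: str
    test: str  # "chi-square", "t" or "mann-whitney"
    statistic: float
    df: float | None
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def chi_square_test(
    table: ContingencyTable | np.ndarray, variable: str = ""
) -> GroupComparison:
    """Pearson chi-square on an r x c table, without continuity correction."""
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    res = stats.chi2_contingency(table.counts, correction=False)
    return GroupComparison(
        variable=variable,
        test="chi-square",
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
    )


def students_t_test(x, y, variable: str = "") -> GroupComparison:
    """Two-sample pooled-variance (equal-variance) t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) != np.mean(y):
            raise DegenerateInputError("zero pooled variance with unequal means")
        return GroupComparison(variable, "t", 0.0, float(x.size + y.size - 2), 1.0)
    res = stats.ttest_ind(x, y, equal_var=True)
    return GroupComparison(
        variable=variable,
        test="t",
        statistic=float(res.statistic),
        df=float(x.size + y.size - 2),
        p=float(res.pvalue),
    )


def mann_whitney_u(x, y, variable: str = "") -> GroupComparison:
    """Mann-Whitney U, exact for small untied samples, else normal approximation.

    The exact null distribution is used when both groups have at most 20
    observations and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs at least 1 value")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        test="mann-whitney",
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
    )


def _count_matrix(records: list[ClinicalRecord], variable: str) -> np.ndarray:
    levels = CLINICAL_COLUMNS[variable]
    classes = ("mutant", "wildtype")
    counts = np.zeros((len(levels), len(classes)), dtype=int)
    for rec in records:
        counts[levels.index(getattr(rec, variable)), classes.index(rec.idh)] += 1
    return counts


def crosstab(records: list[ClinicalRecord], variable: str) -> ContingencyTable:
    """Levels x IDH-class (mutant, wildtype) contingency table for one sign."""
    return ContingencyTable(
        _count_matrix(records, variable),
        row_labels=CLINICAL_COLUMNS[variable],
        col_labels=("mutant", "wildtype"),
    )


def format_p(p: float) -> str:
    """Three-decimal p-value string, '<.001' below 0.0005."""
    if p < 0.0005:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"


def build_table1(
    records: list[ClinicalRecord], shapiro_alpha: float = 0.05
) -> pd.DataFrame:
    """Assemble the participant-characteristics table with per-variable tests.

    Quantitative variables (age) report class mean +/- SD and use the t test
    when both classes pass Shapiro-Wilk at ``shapiro_alpha``, else
    Mann-Whitney; categorical variables report n (%) per level (percentages
    recomputed from counts) and use the uncorrected chi-square test.
    """
    frame = cohort_to_frame(records)
    classes = ("mutant", "wildtype")
    if set(frame["idh"]) != set(classes):
        raise ValueError("both IDH classes must be present")
    by_class = {c: frame[frame["idh"] == c] for c in classes}
    rows = []

    age = {c: by_class[c]["age"].to_numpy() for c in classes}
    pooled_age = np.concatenate(list(age.values()))
    if np.ptp(pooled_age) == 0:
        cmp_age = GroupComparison("age", "t", 0.0, float(pooled_age.size - 2), 1.0)
    elif all(
        np.ptp(a) > 0 and stats.shapiro(a).pvalue >= shapiro_alpha for a in age.values()
    ):
        cmp_age = students_t_test(age["mutant"], age["wildtype"], "age")
    else:
        cmp_age = mann_whitney_u(age["mutant"], age["wildtype"], "age")
    rows.append(
        {
            "variable": "age",
            "level": "",
            "mutant": f"{age['mutant'].mean():.2f}±{age['mutant'].std(ddof=1):.2f}",
            "wildtype": f"{age['wildtype'].mean():.2f}±{age['wildtype'].std(ddof=1):.2f}",
            "test": cmp_age.test,
            "p": cmp_age.p,
            "P value": format_p(cmp_age.p),
        }
    )

    for var, levels in CLINICAL_COLUMNS.items():
        counts = _count_matrix(records, var)
        # levels absent from the whole cohort carry no information; drop them
        # from the test (the displayed rows keep their zero counts)
        occupied = counts.sum(axis=1) > 0
        if occupied.sum() >= 2:
            trimmed = ContingencyTable(
                counts[occupied],
                tuple(np.array(levels)[occupied]),
                ("mutant", "wildtype"),
            )
            cmp_var = chi_square_test(trimmed, var)
        else:
            cmp_var = GroupComparison(var, "chi-square", 0.0, 0.0, 1.0)
        for i, level in enumerate(levels):
            cells = {}
            for j, c in enumerate(classes):
                n = int(counts[i, j])
                total = int(counts[:, j].sum())
                cells[c] = f"{n} ({100.0 * n / total:.1f}%)"
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "mutant": cells["mutant"],
                    "wildtype": cells["wildtype"],
                    "test": cmp_var.test if i == 0 else "",
                    "p": cmp_var.p if i == 0 else np.nan,
                    "P value": format_p(cmp_var.p) if i == 0 else "",
                }
            )
    return pd.DataFrame(rows)
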