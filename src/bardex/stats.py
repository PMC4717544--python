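"""Univariate cohort statistics: group comparison and tertile tables.

Categorical covariates are compared between the reoperation groups with a
two-sided Fisher exact test computed here by direct hypergeometric
enumeration (minimum-likelihood rule: the p-value sums the probabilities of
all tables, under fixed margins, no more likely than the observed one).
Continuous covariates use the pooled-variance two-sample t test.  Across
displacement-index tertiles, continuous covariates use one-way ANOVA and
categorical ones the Pearson chi-square test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bdi import BDIResult, TertileAssignment
from .errors import ValidationError
from .grading import grade_displacement
from .io import PatientRecord

log = logging.getLogger("bardex.stats")

_FISHER_REL_TOL = 1e-7  # relative slack for the <= comparison of point probs


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows are categories, columns the two groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("contingency table is all zero")


@dataclass(frozen=True)
class ComparisonReport:
    variable: str
    summaries: dict[str, str]  # per-group display summaries
    test: str
    statistic: float | None
    df: float | None
    p_value: float


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Enumerates the hypergeometric support of the top-left cell under fixed
    margins using log-factorials, and sums the point probabilities that do
    not exceed the observed table's probability (within a relative tolerance
    of 1e-7, which absorbs floating-point noise among exactly tied tables).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    lf = [math.lgamma(k + 1) for k in range(n + 1)]

    def log_prob(x: int) -> float:
        # P(A = x | margins) for cells (x, r1-x / c1-x, r2-c1+x)
        return (
            lf[r1]
            + lf[r2]
            + lf[c1]
            + lf[n - c1]
            - lf[n]
            - lf[x]
            - lf[r1 - x]
            - lf[c1 - x]
            - lf[r2 - (c1 - x)]
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_prob(x))
        if px <= p_obs * (1.0 + _FISHER_REL_TOL):
            total += px
    return min(total, 1.0)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def t_test_pooled_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TTestResult:
    """Pooled-variance two-sample Student t test from summary statistics.

    df = n1 + n2 - 2; the p-value is two-sided.  When both groups have zero
    variance: equal means give p = 1 by convention, unequal means a
    degenerate p = 0 (logged).
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("t test needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    if sd1 == 0.0 and sd2 == 0.0:
        if mean1 == mean2:
            return TTestResult(0.0, float(df), 1.0)
        log.warning("degenerate t test: zero variance, unequal means")
        t = math.inf if mean1 > mean2 else -math.inf
        return TTestResult(t, float(df), 0.0)
    r = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TTestResult(float(r.statistic), float(df), float(r.pvalue))


def t_test_pooled(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance t test from raw samples (missing values dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    return t_test_pooled_from_stats(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def chi_square(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if (obs < 0).any():
        raise ValidationError("chi_square: negative counts")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("chi_square: zero row or column margin")
    res = sps.chi2_contingency(obs, correction=False)
    if (res.expected_freq < 5).any():
        log.warning("chi_square: expected count < 5 in some cell; "
                    "asymptotic p-value may be unreliable")
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across >= 2 groups of raw values."""
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            raise ValidationError("anova_oneway: every group needs n >= 2")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValidationError("anova_oneway: need >= 2 groups")
    k = len(cleaned)
    n_total = sum(len(g) for g in cleaned)
    res = sps.f_oneway(*cleaned)
    f = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(f):  # all values identical across every group
        f, p = 0.0, 1.0
    return AnovaResult(f, k - 1, n_total - k, p)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, p) with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    r = sps.pearsonr(x[keep], y[keep])
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# cohort-level report tables
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = [
    ("age", "Age (years)"),
    ("bmi", "BMI (kg/m^2)"),
    ("height_m", "Height (m)"),
    ("weight_kg", "Weight (kg)"),
    ("pre_hi", "Pre-op Haller index"),
    ("post_hi", "Post-op Haller index"),
    ("diff_hi", "Haller index change (pre - post)"),
]


def patient_group(patient: PatientRecord, label_by: str = "grade") -> str:
    """Group label A/B of a patient, from the displacement grade (default)
    or from the actual reoperation outcome (``label_by="reoperated"``)."""
    if label_by == "grade":
        return grade_displacement(patient.flags).group
    if label_by == "reoperated":
        return "B" if patient.reoperated else "A"
    raise ValidationError(f"unknown label_by {label_by!r}")


def _covariate_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "sex": [p.sex for p in patients],
            "height_m": [p.height_m for p in patients],
            "weight_kg": [p.weight_kg for p in patients],
            "bmi": [p.bmi for p in patients],
            "pre_hi": [p.pre_hi for p in patients],
            "post_hi": [p.post_hi for p in patients],
            "pectus_type": [p.pectus_type for p in patients],
            "n_bars": [p.n_bars for p in patients],
            "grade": [grade_displacement(p.flags).category for p in patients],
        }
    )
    df["diff_hi"] = df["pre_hi"] - df["post_hi"]
    return df


def _mean_sd(values: pd.Series) -> str:
    v = values.dropna()
    if len(v) == 0:
        return "n/a"
    return f"{v.mean():.1f} ± {v.std(ddof=1):.1f}"


def compare_groups(
    patients: Sequence[PatientRecord], label_by: str = "grade"
) -> list[ComparisonReport]:
    """Univariate comparison of patient covariates between groups A and B.

    Continuous covariates (age, BMI, height, weight, pre/post/diff Haller
    index) are tested with the pooled t test; categorical ones (sex, pectus
    type, number of bars) with the Fisher exact test.  Missing values are
    excluded per variable.
    """
    df = _covariate_frame(patients)
    df["group"] = [patient_group(p, label_by) for p in patients]
    in_a = df["group"] == "A"
    in_b = df["group"] == "B"
    if not in_a.any() or not in_b.any():
        raise ValidationError("compare_groups: a group is empty")
    reports: list[ComparisonReport] = []
    for col, name in CONTINUOUS_VARS:
        xa, xb = df.loc[in_a, col], df.loc[in_b, col]
        r = t_test_pooled(xa.to_numpy(), xb.to_numpy())
        reports.append(
            ComparisonReport(
                variable=name,
                summaries={
                    "All": _mean_sd(df[col]),
                    "A": _mean_sd(xa),
                    "B": _mean_sd(xb),
                },
                test="pooled t",
                statistic=r.t,
                df=r.df,
                p_value=r.p_value,
            )
        )
    categorical = [
        ("sex", "Sex", ("male", "female")),
        ("pectus_type", "Pectus type", ("symmetric", "asymmetric")),
        ("n_bars", "No. of inserted bars", (1, 2)),
    ]
    for col, name, levels in categorical:
        tab = ContingencyTable2x2(
            a=int(((df[col] == levels[0]) & in_a).sum()),
            b=int(((df[col] == levels[0]) & in_b).sum()),
            c=int(((df[col] == levels[1]) & in_a).sum()),
            d=int(((df[col] == levels[1]) & in_b).sum()),
        )
        p = fisher_exact_2x2(tab)
        reports.append(
            ComparisonReport(
                variable=name,
                summaries={
                    "All": f"{levels[0]}: {tab.a + tab.b}, {levels[1]}: {tab.c + tab.d}",
                    "A": f"{levels[0]}: {tab.a}, {levels[1]}: {tab.c}",
                    "B": f"{levels[0]}: {tab.b}, {levels[1]}: {tab.d}",
                },
                test="Fisher exact",
                statistic=None,
                df=None,
                p_value=p,
            )
        )
    return reports


def tertile_table(
    patients: Sequence[PatientRecord],
    results: Sequence[BDIResult],
    assignment: TertileAssignment,
) -> list[ComparisonReport]:
    """Characterize the displacement-index tertiles (unit: bar).

    Every bar inherits its patient's covariates.  Continuous covariates are
    compared across the three tertiles by one-way ANOVA, categorical ones
    (sex, pectus type, displacement grade, number of bars) by chi-square.
    """
    cov = _covariate_frame(patients).set_index("patient_id")
    rows = []
    for r in results:
        t = assignment.labels.get(r.bar_id)
        if t is None:
            raise ValidationError(f"bar {r.bar_id!r} missing from tertile labels")
        row = cov.loc[r.patient_id].to_dict()
        row["tertile"] = t
        rows.append(row)
    df = pd.DataFrame(rows)
    sizes = df["tertile"].value_counts()
    if sorted(sizes.index) != [1, 2, 3]:
        raise ValidationError("tertile_table: an empty tertile")
    reports: list[ComparisonReport] = []
    for col, name in CONTINUOUS_VARS:
        groups = [df.loc[df["tertile"] == t, col].to_numpy() for t in (1, 2, 3)]
        r = anova_oneway(groups)
        reports.append(
            ComparisonReport(
                variable=name,
                summaries={
                    f"T{t}": _mean_sd(df.loc[df["tertile"] == t, col])
                    for t in (1, 2, 3)
                },
                test="one-way ANOVA",
                statistic=r.F,
                df=float(r.df_between),
                p_value=r.p_value,
            )
        )
    categorical = [
        ("sex", "Sex"),
        ("pectus_type", "Pectus type"),
        ("grade", "Displacement grade"),
        ("n_bars", "No. of inserted bars"),
    ]
    for col, name in categorical:
        ct = pd.crosstab(df[col], df["tertile"])
        # drop all-zero rows (levels absent from the cohort)
        ct = ct.loc[ct.sum(axis=1) > 0]
        r = chi_square(ct.to_numpy())
        reports.append(
            ComparisonReport(
                variable=name,
                summaries={
                    f"T{t}": ", ".join(
                        f"{idx}: {ct.at[idx, t]}" for idx in ct.index
                    )
                    for t in ct.columns
                },
                test="chi-square",
                statistic=r.statistic,
                df=float(r.df),
                p_value=r.p_value,
            )
        )
    return reports


def reports_frame(reports: Iterable[ComparisonReport]) -> pd.DataFrame:
    """Flatten comparison reports to a writable table."""
    rows = []
    for r in reports:
        row: dict[str, object] = {"variable": r.variable}
        for k, v in r.summaries.items():
            row[f"summary_{k}"] = v
        row.update(
            test=r.test,
            statistic=r.statistic,
            df=r.df,
            p_value=r.p_value,
        )
        rows.append(row)
    return pd.DataFrame(rows)
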