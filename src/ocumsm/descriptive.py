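"""Descriptive summaries and univariate exact tests.

Patients are grouped by the worst-condition acute ocular severity score as
Grade 0, Grade 1 and Grade 2/3 (severe and very severe pooled).  Hypothesis
tests compare Grade 0/1 against Grade 2/3: the Wilcoxon rank-sum test for
continuous variables and Fisher's exact test for categorical variables.

Fisher's exact test is implemented by margin-fixed enumeration with the
probability-mass ordering (the two-sided p-value sums the probabilities of
all tables no more probable than the observed one); the r x c generalisation
(Freeman-Halton) enumerates the free cells recursively under both margins.
The mid-p and tail-doubling conventions would give different values and are
not used.

The Wilcoxon test uses the exact permutation distribution of the rank sum
(midranks under ties) for combined sample sizes up to 20 and otherwise a
tie-corrected normal approximation with a 0.5 continuity correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .event_history import PatientRecord

__all__ = [
    "ContingencyTable",
    "GroupedSummary",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "summarize_by_grade",
    "grade_group_compare",
    "GRADE_GROUPS",
]

#: worst-grade display groups: label -> set of grades
GRADE_GROUPS = {"Grade 0": (0,), "Grade 1": (1,), "Grade 2/3": (2, 3)}


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be two-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


def _log_table_prob(table: np.ndarray, lg_margins: float) -> float:
    """Log multivariate hypergeometric probability given fixed margins."""
    return lg_margins - gammaln(table + 1.0).sum()


def fisher_exact(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    max_tables: int = 10_000_000,
) -> float:
    """Two-sided Fisher exact p-value for an r x c table (Freeman-Halton).

    Enumerates every table with the observed margins; the p-value is the total
    conditional (multivariate hypergeometric) probability of tables whose
    probability does not exceed the observed table's (within a relative
    tolerance guarding float round-off).  Enumeration is aborted once
    ``max_tables`` tables have been visited.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("Fisher's exact test needs at least a 2x2 table")
    n = int(counts.sum())
    if n < 1:
        raise ValueError("table must contain at least one observation")
    # orient so the recursion runs over the smaller dimension's rows
    if counts.shape[0] > counts.shape[1]:
        counts = counts.T
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        # empty margins carry no information; drop them
        counts = counts[row > 0][:, col > 0]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            return 1.0
        row = counts.sum(axis=1)
        col = counts.sum(axis=0)

    lg_margins = (
        gammaln(row + 1.0).sum() + gammaln(col + 1.0).sum() - gammaln(n + 1.0)
    )
    log_p_obs = _log_table_prob(counts, lg_margins)
    cutoff = log_p_obs + 1e-7

    r, c = counts.shape
    visited = 0
    total = 0.0

    def recurse(i: int, col_left: np.ndarray, log_acc: float):
        nonlocal visited, total
        if i == r - 1:
            visited += 1
            if visited > max_tables:
                raise RuntimeError(
                    f"Freeman-Halton enumeration exceeded {max_tables} tables; "
                    "collapse categories or raise max_tables"
                )
            lp = log_acc + lg_margins - gammaln(col_left + 1.0).sum()
            if lp <= cutoff:
                total += math.exp(lp)
            return
        ri = int(row[i])
        # enumerate row i over compositions bounded by remaining column margins
        def fill(j: int, left: int, cols: np.ndarray, lacc: float):
            if j == c - 1:
                if left <= cols[j]:
                    new_cols = cols.copy()
                    new_cols[j] -= left
                    recurse(i + 1, new_cols, lacc - gammaln(left + 1.0))
                return
            for v in range(min(left, int(cols[j])) + 1):
                new_cols = cols.copy()
                new_cols[j] -= v
                fill(j + 1, left - v, new_cols, lacc - gammaln(v + 1.0))

        fill(0, ri, col_left, log_acc)

    recurse(0, col.astype(np.int64).copy(), 0.0)
    return float(min(total, 1.0))


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 20
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution of the midrank sum when the combined sample
    size is at most ``exact_limit``; otherwise the normal approximation with
    tie-corrected variance and a 0.5 continuity correction toward the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return 1.0
    n1, n2 = len(x), len(y)
    N = n1 + n2
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0
    if N <= exact_limit:
        dev_obs = abs(w_obs - mu)
        count = 0
        n_total = math.comb(N, n1)
        for comb in itertools.combinations(range(N), n1):
            w = ranks[list(comb)].sum()
            if abs(w - mu) >= dev_obs - 1e-9:
                count += 1
        return count / n_total
    # tie-corrected variance
    _vals, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((N) * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    dev = abs(w_obs - mu) - 0.5
    if dev < 0:
        dev = 0.0
    z = dev / math.sqrt(var)
    return float(2.0 * stats.norm.sf(z))


# ---------------------------------------------------------------------------
# grouped summaries


@dataclass
class GroupedSummary:
    """Per-grade-group summary of one variable (count/% or median/range)."""

    variable: str
    kind: str  # "categorical" | "continuous"
    groups: dict  # label -> {"n": int, ...}
    denominator: str = "all"  # "all" | "non_missing"
    p_value: Optional[float] = None


def _worst_group(rec: PatientRecord) -> str:
    for label, grades in GRADE_GROUPS.items():
        if rec.grade_worst.value in grades:
            return label
    raise AssertionError


CONTINUOUS_VARIABLES = {
    "age_years": lambda r: r.age_years,
    "days_onset_to_initial": lambda r: r.days_onset_to_initial,
    "severity_subscore": lambda r: r.severity_subscore,
}

FLAG_VARIABLES = {
    "sex_male": lambda r: r.sex == "male",
    "diagnosis_ten": lambda r: r.diagnosis == "TEN",
    "drug_nsaids": lambda r: r.drug_nsaids,
    "drug_cold_remedies": lambda r: r.drug_cold_remedies,
    "drug_antibiotics": lambda r: r.drug_antibiotics,
    "drug_anticonvulsants": lambda r: r.drug_anticonvulsants,
    "drug_gout": lambda r: r.drug_gout,
    "died": lambda r: r.died,
}

OUTCOME_VARIABLES = {
    "sequelae": (lambda r: r.sequelae, ["present"]),
    "visual_disturbance": (lambda r: r.visual_disturbance, ["20/20-20/200", "worse than 20/200"]),
    "dry_eye": (lambda r: r.dry_eye, ["mild", "moderate", "severe"]),
}


def summarize_by_grade(cohort: Sequence[PatientRecord]) -> dict:
    """Characteristics and outcomes by worst-condition severity group.

    Covariate percentages use all patients in the group as denominator; the
    chronic-outcome variables (sequelae, visual disturbance, dry eye) use the
    non-missing patients of the group, with the number missing reported
    alongside.  Median (range) is reported for continuous variables.
    """
    members = {label: [] for label in GRADE_GROUPS}
    for rec in cohort:
        members[_worst_group(rec)].append(rec)

    summaries: dict[str, GroupedSummary] = {}
    for var, getter in CONTINUOUS_VARIABLES.items():
        groups = {}
        for label, recs in members.items():
            vals = np.array([getter(r) for r in recs], dtype=float)
            groups[label] = {
                "n": len(recs),
                "median": float(np.median(vals)) if len(vals) else float("nan"),
                "min": float(vals.min()) if len(vals) else float("nan"),
                "max": float(vals.max()) if len(vals) else float("nan"),
            }
        summaries[var] = GroupedSummary(var, "continuous", groups)

    for var, getter in FLAG_VARIABLES.items():
        groups = {}
        for label, recs in members.items():
            k = sum(bool(getter(r)) for r in recs)
            n = len(recs)
            groups[label] = {
                "n": n,
                "count": k,
                "percent": 100.0 * k / n if n else float("nan"),
            }
        summaries[var] = GroupedSummary(var, "categorical", groups)

    for var, (getter, categories) in OUTCOME_VARIABLES.items():
        groups = {}
        for label, recs in members.items():
            non_missing = [r for r in recs if getter(r) is not None]
            n_nm = len(non_missing)
            cat_counts = {
                cat: sum(getter(r) == cat for r in non_missing) for cat in categories
            }
            any_count = sum(cat_counts.values())
            groups[label] = {
                "n": len(recs),
                "n_non_missing": n_nm,
                "n_missing": len(recs) - n_nm,
                "categories": cat_counts,
                "any_count": any_count,
                "any_percent": 100.0 * any_count / n_nm if n_nm else None,
            }
        summaries[var] = GroupedSummary(var, "categorical", groups, denominator="non_missing")
    return summaries


def grade_group_compare(cohort: Sequence[PatientRecord], variable: str) -> float:
    """p-value comparing Grade 0/1 with Grade 2/3 on one variable.

    Continuous variables dispatch to the Wilcoxon rank-sum test, categorical
    ones to Fisher's exact test on the 2 x k table of the grade-group split.
    """
    low = [r for r in cohort if r.grade_worst.value <= 1]
    high = [r for r in cohort if r.grade_worst.value >= 2]
    if variable in CONTINUOUS_VARIABLES:
        getter = CONTINUOUS_VARIABLES[variable]
        return wilcoxon_rank_sum(
            [getter(r) for r in low], [getter(r) for r in high]
        )
    if variable in FLAG_VARIABLES:
        getter = FLAG_VARIABLES[variable]
        counts = np.array(
            [
                [sum(bool(getter(r)) for r in g), sum(not getter(r) for r in g)]
                for g in (low, high)
            ]
        )
        return fisher_exact(counts)
    if variable in OUTCOME_VARIABLES:
        getter, categories = OUTCOME_VARIABLES[variable]
        rows = []
        for g in (low, high):
            nm = [r for r in g if getter(r) is not None]
            row = [sum(getter(r) == cat for r in nm) for cat in categories]
            none_count = len(nm) - sum(row)
            rows.append([none_count] + row)
        counts = np.array(rows)
        counts = counts[:, counts.sum(axis=0) > 0]
        return fisher_exact(counts)
    raise ValueError(f"unknown variable {variable!r}")
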