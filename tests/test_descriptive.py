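import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.special import gammaln

from ocumsm.descriptive import (
    GRADE_GROUPS,
    fisher_exact,
    grade_group_compare,
    summarize_by_grade,
    wilcoxon_rank_sum,
)


def brute_force_fisher(counts: np.ndarray) -> float:
    """Independent enumeration oracle: iterate every cell assignment via
    nested products over row compositions and sum probability-ordered mass."""
    counts = np.asarray(counts, dtype=np.int64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    lg_marg = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)

    def log_p(tab):
        return lg_marg - gammaln(np.asarray(tab) + 1.0).sum()

    p_obs = log_p(counts)
    r, c = counts.shape

    def compositions(total, bounds):
        if len(bounds) == 1:
            if total <= bounds[0]:
                yield (total,)
            return
        for v in range(min(total, bounds[0]) + 1):
            for rest in compositions(total - v, bounds[1:]):
                yield (v,) + rest

    total_p = 0.0
    def rec(i, col_left, acc):
        nonlocal total_p
        if i == r:
            if all(v == 0 for v in col_left):
                lp = log_p(acc)
                if lp <= p_obs + 1e-7:
                    total_p += math.exp(lp)
            return
        for comp in compositions(int(row[i]), col_left):
            rec(i + 1, [cl - v for cl, v in zip(col_left, comp)], acc + list(comp))

    rec(0, list(col), [])
    return min(total_p, 1.0)


def test_fisher_symmetric_2x2_is_one():
    assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)


def test_fisher_matches_scipy_on_2x2():
    tables = [
        [[31, 106], [39, 54]],
        [[3, 10], [8, 2]],
        [[0, 5], [7, 1]],
        [[12, 4], [5, 9]],
    ]
    for t in tables:
        assert fisher_exact(t) == pytest.approx(
            sps.fisher_exact(t)[1], rel=1e-9
        )


@pytest.mark.parametrize(
    "table",
    [
        [[3, 2, 4], [1, 5, 2]],
        [[2, 0, 3], [4, 4, 1], [0, 2, 2]],
        [[7, 1], [2, 6], [3, 3]],
        [[1, 2, 3], [3, 2, 1]],
    ],
)
def test_freeman_halton_matches_enumeration_oracle(table):
    assert fisher_exact(table) == pytest.approx(
        brute_force_fisher(np.array(table)), rel=1e-9
    )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=3),
        min_size=2,
        max_size=3,
    ).filter(
        lambda t: len({len(r) for r in t}) == 1
        and sum(map(sum, t)) > 0
        and sum(map(sum, t)) <= 30
    )
)
def test_fisher_invariant_to_permutations(table):
    """Fisher's exact p is unchanged by permuting rows or columns and lies
    in (0, 1]."""
    t = np.array(table)
    p = fisher_exact(t)
    assert 0 < p <= 1 + 1e-12
    perm_rows = t[np.random.RandomState(0).permutation(t.shape[0])]
    assert fisher_exact(perm_rows) == pytest.approx(p, rel=1e-9)
    assert fisher_exact(t.T) == pytest.approx(p, rel=1e-9)


def test_fisher_enumeration_budget():
    with pytest.raises((RuntimeError, ValueError)):
        big = np.full((5, 5), 40)
        fisher_exact(big, max_tables=1000)


def test_wilcoxon_identical_samples():
    with pytest.warns(UserWarning):
        assert wilcoxon_rank_sum([2, 2, 2], [2, 2]) == 1.0


def test_wilcoxon_extreme_separation():
    """{1,2,3} vs {4,5,6}: 2 of the 20 rank assignments are as extreme."""
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_exact_equals_full_enumeration():
    """Exact p equals direct enumeration over all label assignments for
    combined n <= 10, including ties."""
    rng = np.random.default_rng(8)
    for _ in range(6):
        n1, n2 = rng.integers(2, 5), rng.integers(2, 6)
        pooled = rng.integers(0, 6, n1 + n2).astype(float)
        x, y = pooled[:n1], pooled[n1:]
        if np.ptp(pooled) == 0:
            continue
        ranks = sps.rankdata(pooled)
        mu = n1 * (n1 + n2 + 1) / 2
        w_obs = ranks[:n1].sum()
        count = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
                count += 1
        assert wilcoxon_rank_sum(x, y) == pytest.approx(count / total)


def test_wilcoxon_large_sample_matches_reference_approximation():
    rng = np.random.default_rng(3)
    x = rng.integers(0, 15, 40).astype(float)
    y = (rng.integers(0, 15, 35) + 2).astype(float)
    ref = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    ).pvalue
    assert wilcoxon_rank_sum(x, y) == pytest.approx(ref, rel=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-50, 50), min_size=2, max_size=8),
    st.lists(st.integers(-50, 50), min_size=2, max_size=8),
)
def test_wilcoxon_invariant_under_monotone_transform(x, y):
    """The rank-sum p-value depends only on the ordering, so any strictly
    increasing transform (here cubing) leaves it unchanged."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p1 = wilcoxon_rank_sum(x, y)
        f = lambda v: np.asarray(v, dtype=float) ** 3
        p2 = wilcoxon_rank_sum(f(x), f(y))
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_null_p_values_roughly_uniform():
    """p-values under the null are approximately uniform (KS check)."""
    rng = np.random.default_rng(12)
    ps = []
    for _ in range(300):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        ps.append(wilcoxon_rank_sum(x, y))
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_summary_reproduces_outcome_percentages(eligible):
    """Grade 2/3 non-missing denominators: sequelae 53.5%, any visual
    disturbance 20%, any dry eye 48%."""
    s = summarize_by_grade(eligible)
    seq = s["sequelae"].groups["Grade 2/3"]
    assert (seq["any_count"], seq["n_non_missing"]) == (46, 86)
    assert round(seq["any_percent"], 1) == 53.5
    vis = s["visual_disturbance"].groups["Grade 2/3"]
    assert round(vis["any_percent"]) == 20
    dry = s["dry_eye"].groups["Grade 2/3"]
    assert round(dry["any_percent"]) == 48


def test_summary_totals_and_missing_reconcile(eligible):
    s = summarize_by_grade(eligible)
    sizes = {g["n"] for g in [s["sequelae"].groups[k] for k in GRADE_GROUPS]}
    assert sum(s["sequelae"].groups[k]["n"] for k in GRADE_GROUPS) == 230
    missing = [s["sequelae"].groups[k]["n_missing"] for k in GRADE_GROUPS]
    assert missing == [0, 3, 7]
    for k in GRADE_GROUPS:
        g = s["sequelae"].groups[k]
        assert g["n_non_missing"] + g["n_missing"] == g["n"]


def test_grade_group_compare_reproduces_printed_p_values(eligible):
    """The published categorical comparisons (Grade 0/1 vs 2/3) reproduce to
    the printed precision."""
    expected = {
        "drug_nsaids": 0.002,
        "drug_cold_remedies": 0.048,
        "drug_antibiotics": 0.347,
        "drug_anticonvulsants": 0.429,
        "drug_gout": 0.518,
        "sex_male": 0.341,
        "diagnosis_ten": 0.244,
        "died": 0.600,
    }
    for var, target in expected.items():
        assert round(grade_group_compare(eligible, var), 3) == target
    assert grade_group_compare(eligible, "sequelae") < 0.001


def test_grade_group_compare_unknown_variable(eligible):
    with pytest.raises(ValueError, match="unknown variable"):
        grade_group_compare(eligible, "shoe_size")


def test_grade_group_compare_detects_age_shift():
    """A 10-year age shift at n=230 (sd 18) is detected with high power."""
    from ocumsm.event_history import PatientRecord, SeverityGrade

    rng = np.random.default_rng(21)
    cohort = []
    for i in range(230):
        severe = i < 93
        age = rng.normal(50 if severe else 60, 18)
        cohort.append(
            PatientRecord(
                patient_id=str(i), age_years=float(np.clip(age, 5, 90)),
                sex="male", diagnosis="SJS", drug_nsaids=False,
                drug_cold_remedies=False, drug_antibiotics=False,
                drug_anticonvulsants=False, drug_gout=False,
                severity_subscore=5, days_onset_to_initial=3,
                days_initial_to_worst=0,
                grade_initial=SeverityGrade(2 if severe else 0),
                grade_worst=SeverityGrade(2 if severe else 0),
                days_onset_to_last_followup=40, died=False,
            )
        )
    assert grade_group_compare(cohort, "age_years") < 0.05
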