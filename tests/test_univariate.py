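import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cranioshape.univariate import (
    MilestoneRecord,
    bh_discoveries,
    cumulative_incidence,
    logrank_test,
    mann_whitney,
    milestone_frame,
    rout_outliers,
)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def exact_mw_p(x, y):
    """Exhaustive-enumeration oracle for the exact two-sided Mann-Whitney
    p-value (no ties): P(|U' - n1 n2 / 2| >= |u - n1 n2 / 2|) over all
    C(n1+n2, n1) arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    center = n1 * n2 / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        sel = set(combo)
        xs = pooled[list(combo)]
        ys = pooled[[i for i in range(n1 + n2) if i not in sel]]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            extreme += 1
    return extreme / total


def test_mw_stated_exact_case():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "mann_whitney_exact"


def test_mw_matches_enumeration_oracle(rng):
    for _ in range(5):
        x = rng.permutation(np.arange(10, dtype=float))[:4]
        y = rng.permutation(np.arange(10, 20, dtype=float))[:5] + rng.uniform(-8, 0)
        if np.intersect1d(x, y).size:
            continue
        assert mann_whitney(x, y).p_value == pytest.approx(exact_mw_p(x, y), abs=1e-12)


def test_mw_identical_multisets():
    res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.statistic == 8  # n^2 / 2
    assert res.p_value == 1.0


def test_mw_asymptotic_close_to_exact_at_n6():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(6)
    y = rng.standard_normal(6) + 0.5
    exact = mann_whitney(x, y)  # combined n = 12 -> exact path
    assert exact.method == "mann_whitney_exact"
    from scipy import stats

    approx = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert abs(exact.p_value - approx.pvalue) <= 0.01


def test_mw_monotone_transform_invariance(rng):
    x = rng.standard_normal(7)
    y = rng.standard_normal(9) + 0.3
    p1 = mann_whitney(x, y).p_value
    p2 = mann_whitney(np.exp(x), np.exp(y)).p_value
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_mw_empty_sample_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_step_up_stated_example():
    flags = bh_discoveries([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
    assert flags.tolist() == [True, True, True, True, False]


def test_bh_degenerate_inputs():
    assert not bh_discoveries(np.ones(6), q=0.05).any()
    assert bh_discoveries(np.zeros(6), q=0.05).all()


@settings(deadline=None, max_examples=50)
@given(
    st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
    st.floats(0.01, 0.2),
)
def test_bh_never_fewer_than_bonferroni(pvals, q):
    p = np.asarray(pvals)
    bh = bh_discoveries(p, q)
    bonferroni = p <= q / p.size
    assert np.all(bh[bonferroni])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(12)
    p = rng.uniform(0, 1, size=25) ** 2
    ours = bh_discoveries(p, q=0.05)
    theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
    assert np.array_equal(ours, theirs)


# ---------------------------------------------------------------------------
# ROUT-style outlier screen
# ---------------------------------------------------------------------------

def test_rout_tight_cluster_no_outliers():
    flags = rout_outliers([10.0, 10.1, 9.9, 10.05, 9.95], q=0.01)
    assert not flags.any()


def test_rout_single_gross_outlier_flagged():
    values = [10.0, 10.1, 9.9, 10.05, 9.95, 25.0]
    flags = rout_outliers(values, q=0.01)
    assert flags.tolist() == [False, False, False, False, False, True]


def test_rout_affine_invariance(rng):
    values = np.concatenate([rng.normal(5, 0.2, size=10), [12.0]])
    base = rout_outliers(values, q=0.01)
    assert np.array_equal(base, rout_outliers(3.5 * values - 40.0, q=0.01))
    assert np.array_equal(base, rout_outliers(-2.0 * values + 7.0, q=0.01))


def test_rout_minimum_n():
    with pytest.raises(ValueError):
        rout_outliers([1.0, 2.0, 3.0], q=0.01)


# ---------------------------------------------------------------------------
# logrank
# ---------------------------------------------------------------------------

def _records(groups_days, observed_through=15):
    records = []
    i = 0
    for group, days in groups_days.items():
        for day in days:
            records.append(
                MilestoneRecord(f"m{i}", group, "eye_opening", day, observed_through)
            )
            i += 1
    return milestone_frame(records)


def test_logrank_identical_groups_statistic_zero():
    df = _records({"A": [3, 5, 7], "B": [3, 5, 7]})
    res = logrank_test(df, "A", "B")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_logrank_toy_matches_hand_mantel_haenszel():
    # A: days 2,3; B: days 4,5.  Hand computation over distinct days:
    # day 2: O-E = 1 - 2/4, V = (2/4)(2/4)(3/3) = 1/4
    # day 3: O-E = 1 - 1/3, V = (1/3)(2/3)(2/2) = 2/9
    # days 4, 5: group A no longer at risk, O-E = 0, V = 0
    # chi2 = (7/6)^2 / (17/36) = 49/17
    df = _records({"A": [2, 3], "B": [4, 5]})
    res = logrank_test(df, "A", "B")
    assert res.statistic == pytest.approx(49 / 17, abs=1e-12)


def test_logrank_label_swap_invariance():
    df = _records({"A": [2, 4, 9], "B": [3, 3, 8, 12]})
    r1 = logrank_test(df, "A", "B")
    r2 = logrank_test(df, "B", "A")
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_logrank_agrees_with_lifelines_on_random_data():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(99)
    for _ in range(50):
        na, nb = rng.integers(4, 10, size=2)
        days_a = rng.integers(1, 14, size=na)
        days_b = rng.integers(1, 14, size=nb) + rng.integers(0, 3)
        censored_a = rng.random(na) < 0.15
        censored_b = rng.random(nb) < 0.15
        records = []
        for i, (day, cens) in enumerate(zip(days_a, censored_a)):
            records.append(
                MilestoneRecord(f"a{i}", "A", "m", None if cens else int(min(day, 15)), 15)
            )
        for i, (day, cens) in enumerate(zip(days_b, censored_b)):
            records.append(
                MilestoneRecord(f"b{i}", "B", "m", None if cens else int(min(day, 15)), 15)
            )
        df = milestone_frame(records)
        if df["event_day"].notna().sum() == 0:
            continue
        ours = logrank_test(df, "A", "B")
        times = df["event_day"].fillna(df["observed_through"]).astype(float)
        events = df["event_day"].notna().astype(int)
        in_a = df["group"] == "A"
        theirs = ll_logrank(
            times[in_a], times[~in_a], event_observed_A=events[in_a],
            event_observed_B=events[~in_a],
        )
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-8)


def test_logrank_requires_both_groups():
    df = _records({"A": [2, 3]})
    with pytest.raises(ValueError):
        logrank_test(df, "A", "B")


# ---------------------------------------------------------------------------
# cumulative incidence
# ---------------------------------------------------------------------------

def test_cumulative_incidence_single_day():
    df = _records({"A": [5, 5, 5, 5]})
    table = cumulative_incidence(df, "A")
    assert (table.loc[table["day"] < 5, "percent"] == 0.0).all()
    assert (table.loc[table["day"] >= 5, "percent"] == 100.0).all()
    assert table.loc[table["day"].isin([4, 5]), "sem"].tolist() == [0.0, 0.0]


def test_cumulative_incidence_step_counting():
    df = _records({"A": [2, 2, 4, 6]})
    table = cumulative_incidence(df, "A").set_index("day")["percent"]
    assert table[2] == table[3] == 50.0
    assert table[4] == table[5] == 75.0
    assert table[6] == 100.0
    assert (np.diff(table.to_numpy()) >= 0).all()


def test_milestone_record_validates_window():
    with pytest.raises(ValueError):
        MilestoneRecord("x", "A", "eye_opening", 20, observed_through=15)
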